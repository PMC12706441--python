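"""Small English vocabulary used as the dictionary for free-text plausibility.

The list mixes high-frequency function words with survey / clinical-practice
vocabulary so that short open-ended answers from genuine respondents score a
high dictionary ratio while keyboard-mash or digit-laden junk scores near zero.
It is intentionally compact: the free-text evaluator only needs a token-level
"looks like English" signal, not real language understanding.
"""

from __future__ import annotations

_WORD_TEXT = """
a about above access additional address adolescent adult advice after again
age all allow almost also although always am an and annual another answer any
appointment approach are area around as ask aspect assess at available
abortion b baby based basic be because been before being believe best better
between birth both but by c call can cannot care case center certain change
check child children clinic clinical close college comfortable comment
community complete complex concern condition confirm consider consult contact
continue contraception contraceptive cost could counselling counseling country
couple course cover current currently d daily data day days decision demand
depend describe detail did difficult direct discuss do doctor does done dose
down due during e each early education eligible else emergency employment end
enough ensure equipment etc even evening ever every exam examination example
expect experience explain extra f family far feel fees fellow felt few fill
find first five focus follow for form found four free frequent friendly from
full further future g gave general generally get give given go good great
group gynaecology gynecology h had hard has have health healthcare help her
here high him his home hospital hour hours how however i if important in
include including income increase information initial insert insertion
instead insurance intrauterine is issue it its iud j job just k keep kind
knew know l lab labour large last late later learn leave less letter level
like limited list little local location long longer look low m made mainly
make manage management many may maybe medical medicare medication medicine
meet member mention method midwife might minute minutes miscarriage monday
month monthly more morning most mostly much must my n name near need needs
never new next no none normal not note nothing now number nurse nursing o
obstetrics of off offer office often old on once one ongoing only open
operate option options or order other our out outside over own p part
partner past patient patients pay people per perform perhaps period person
personal pharmacy phone physician pill place plan please point policy poor
position possible post practice practitioner pregnancy pregnant prefer
prescribe prescription present pretty prevention previous primary private
problem procedural procedure process program provide provider providing
public q qualified question questions quick quite r range rarely rather
reach read really reason receive receive recent recently referral refer
regarding region regular regularly related remote remuneration report
request require research resident resource respond response rest result
return review right risk routine rural s safe same saw say schedule school
second see seen self semester send service services session set seven
several she should side simple since site situation six small so some
someone something sometimes soon sorry sort speak special specialist
specialty staff stage standard start state stay still student study such
supply support sure surgery survey system t take team telehealth telephone
tell ten term test testing than that the their them then there these they
thing think third this those though three through time times to today told
too took topic total town training transfer travel treat treatment trimester
trust try twice two type typical u ultrasound under understand unit until
up upon urban urgent us use usually v vaccine various very virtual visit
visits w wait want was watch way we week weekly weeks well went were what
when where whether which while who whole why will willing wish with within
without woman women work working would x y year years yes yet you young your
z zero
"""

WORDS: frozenset[str] = frozenset(_WORD_TEXT.split())


def dictionary_ratio(tokens: list[str]) -> float:
    """Fraction of tokens found in the built-in vocabulary (0.0 for no tokens)."""
    if not tokens:
        return 0.0
    hits = sum(1 for t in tokens if t.lower() in WORDS)
    return hits / len(tokens)
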