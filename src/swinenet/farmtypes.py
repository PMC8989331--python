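"""Farm typology, sectors, animal categories and routing conventions.

The French pig industry distinguishes a breeding sector (nucleus and
multiplier herds supplying genetics, plus boar stations) from a growing
sector covering the production stages from farrowing to fattening.  Farm
types are the standard French codes:

==== =======================================
code meaning
==== =======================================
FA   farrower (naisseur)
PW   post-weaner
FI   finisher (engraisseur)
FF   farrow-to-finish
FPW  farrower/post-weaner
PWF  post-weaner/finisher
MU   multiplier
NU   nucleus (selection herd)
BS   boar station (insemination centre)
NI   non-industry holding (hobby, other)
==== =======================================
"""

from __future__ import annotations

FARM_TYPES = ("FA", "PW", "FI", "FF", "FPW", "PWF", "MU", "NU", "BS", "NI")

BREEDING_TYPES = frozenset({"MU", "NU", "BS"})
GROWING_TYPES = frozenset({"FA", "PW", "FI", "FF", "FPW", "PWF"})
INDUSTRY_TYPES = BREEDING_TYPES | GROWING_TYPES

ANIMAL_CATEGORIES = ("piglet", "growing_pig", "barrow", "sow", "cull")

#: active-holding type mix observed in the national movement database
#: (fractions of active holdings; the residual 6.39% is non-industry).
DEFAULT_TYPE_PROPORTIONS = {
    "MU": 0.0137,
    "NU": 0.0057,
    "BS": 0.0033,
    "FA": 0.0255,
    "FPW": 0.0209,
    "FF": 0.3420,
    "PW": 0.0056,
    "PWF": 0.1458,
    "FI": 0.3736,
    "NI": 0.0639,
}

#: which husbandry areas a farm of a given type operates.
#: repro = gestation/farrowing, postwean = growing/weaning, fatten = finishing.
TYPE_AREAS = {
    "FA": frozenset({"repro"}),
    "PW": frozenset({"postwean"}),
    "FI": frozenset({"fatten"}),
    "FPW": frozenset({"repro", "postwean"}),
    "PWF": frozenset({"postwean", "fatten"}),
    "FF": frozenset({"repro", "postwean", "fatten"}),
    "MU": frozenset({"repro", "postwean"}),
    "NU": frozenset({"repro", "postwean"}),
    "BS": frozenset(),
    "NI": frozenset(),
}

#: inverse map used when a declared type is promoted to cover every area the
#: holding actually reports.  repro+fatten without postwean has no code of its
#: own and promotes to farrow-to-finish.
AREAS_TO_TYPE = {
    frozenset({"repro"}): "FA",
    frozenset({"postwean"}): "PW",
    frozenset({"fatten"}): "FI",
    frozenset({"repro", "postwean"}): "FPW",
    frozenset({"postwean", "fatten"}): "PWF",
    frozenset({"repro", "fatten"}): "FF",
    frozenset({"repro", "postwean", "fatten"}): "FF",
}

#: (animal_category, origin farm type) pairs that are biologically implausible
#: and dropped by the consistency filter: a farrowing-only farm cannot ship
#: barrows, a finishing-only farm cannot ship piglets, etc.
DEFAULT_INCONSISTENT_PAIRS = frozenset(
    {
        ("barrow", "FA"),
        ("barrow", "FPW"),
        ("piglet", "FI"),
        ("piglet", "PWF"),
        ("growing_pig", "FA"),
        ("sow", "FI"),
        ("sow", "PW"),
        ("sow", "PWF"),
    }
)


def sector_of(farm_type: str) -> str:
    """Industry sector of a farm type: ``breeding`` (MU/NU/BS) or ``growing``."""
    return "breeding" if farm_type in BREEDING_TYPES else "growing"
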