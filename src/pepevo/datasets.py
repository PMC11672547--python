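"""Reference scaffolds and published inhibition constants.

The bicyclic peptide families this package targets are phage-selected
inhibitors of human urokinase-type plasminogen activator (huPA, the
UK18/UK140 families) and of activated coagulation factor XIIa. The full
family tables live in an external repository; what ships here are the
scaffold definitions and the individually published Ki measurements of
named variants, which drive the worked fold-change examples.
"""

from __future__ import annotations

from .seq_core import Scaffold

NM = 1e-9


def uk18_scaffold() -> Scaffold:
    """The 17-residue huPA bicyclic template: two six-residue loops flanked
    by three cysteines, with alanine/glycine termini."""
    return Scaffold(L=17, fixed={1: "A", 2: "C", 9: "C", 16: "C", 17: "G"},
                    name="UK18-family")


def fxiia_scaffold() -> Scaffold:
    """The 14-residue factor-XIIa family template (three pinned cysteines)."""
    return Scaffold(L=14, fixed={1: "A", 2: "C", 7: "C", 13: "C", 14: "G"},
                    name="FXIIa-family")


#: Published Ki measurements (molar) of named bicyclic peptide variants.
PUBLISHED_KI_MOLAR: dict[str, float] = {
    # huPA, UK18 family and its in-silico descendants
    "UK18": 53 * NM,
    "UK957": 7.4 * NM,
    "UK961": 16.2 * NM,
    "UK970": 4.3 * NM,
    "UK971": 6.4 * NM,
    "UK972": 14.8 * NM,
    "UK973": 15.3 * NM,
    # huPA leave-out validation members
    "UK115": 610 * NM,
    "UK132": 470 * NM,
    # huPA, UK140 family and descendants
    "UK140": 202 * NM,
    "UK974": 363 * NM,
    "UK975": 874 * NM,
    # factor XIIa leave-out validation members
    "FXII617": 12 * NM,
    "FXII618": 12 * NM,
}

#: Selection thresholds (molar) reported for the published campaigns,
#: useful as order-of-magnitude sanity scales only.
PUBLISHED_THRESHOLDS_MOLAR: dict[str, float] = {
    "uk18_family_round1": 0.92e-6,
    "uk18_family_round2": 0.38e-6,
    "uk140_family": 1.97e-6,
    "uk140_family_depleted": 2.16e-6,
    "fxiia_family_depleted": 0.12e-6,
}
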