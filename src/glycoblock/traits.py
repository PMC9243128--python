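"""Derived glycosylation traits computed from the 39-peak panel.

Derived traits summarise peaks sharing a structural feature — number of
antennae, galactoses, sialic acids, and fucose position.  The exact
peak-to-structure assignment is laboratory-specific; the default table
shipped here follows standard plasma-N-glycome UPLC conventions (it is a
convention-based default, explicitly overridable via a trait-definition
file).  It defines 21 traits in six families:

============================  ===========================================
family                        traits
============================  ===========================================
branching                     A2, TRIA, TETRA
degree of branching           LB, HB
galactosylation               G0, G1, G2, G3, G4
sialylation                   S0, S1, S2, S3, S4
sialylation of biantennary    A2S0, BAMS, BADS
fucose position               CF, AF, A2F
============================  ===========================================

Sum traits are percentages of total integrated area (the input peaks are
compositional); within-biantennary traits are ratios expressed as percent
of the biantennary total.
"""

from __future__ import annotations

import numpy as np

from glycoblock.datamodel import (
    DEFAULT_PEAK_PANEL,
    DerivedTraitMatrix,
    GlycanPeakMatrix,
    TraitDefinitionTable,
    parse_formula,
)
from glycoblock.errors import FormulaError

__all__ = ["default_trait_table", "compute_traits", "DEFAULT_TRAIT_ROWS"]


def _gp(indices) -> str:
    return "+".join(f"GP{i}" for i in indices)


# Structural assignment (convention-based): GP1-GP2 monoantennary,
# GP3-GP20 biantennary, GP21-GP25 & GP27-GP33 triantennary,
# GP26 & GP34-GP39 tetraantennary.
_MONO = (1, 2)
_BI = tuple(range(3, 21))
_TRI = (21, 22, 23, 24, 25, 27, 28, 29, 30, 31, 32, 33)
_TETRA = (26, 34, 35, 36, 37, 38, 39)

_G0 = (1, 2, 3, 4, 5)
_G1 = (6, 7, 8, 9, 13)
_G2 = (10, 11, 12, 14, 15, 16, 17, 18, 19, 20)
_G3 = _TRI
_G4 = _TETRA

_S0 = tuple(range(1, 13))
_S1 = (13, 14, 15, 16, 21)
_S2 = (17, 18, 19, 20, 22, 23, 26)
_S3 = (24, 25, 27, 28, 29, 30, 31, 32, 33, 34, 35)
_S4 = (36, 37, 38, 39)

_CORE_FUC = (2, 4, 5, 8, 9, 11, 12, 15, 16, 19, 20, 28)
_ANT_FUC = (25, 29, 33, 35, 38)
_BI_FUC = (4, 5, 8, 9, 11, 12, 15, 16, 19, 20)

_BI_S0 = tuple(i for i in _BI if i in _S0)
_BI_S1 = tuple(i for i in _BI if i in _S1)
_BI_S2 = tuple(i for i in _BI if i in _S2)

#: (trait_id, family, formula) rows of the default convention-based table.
DEFAULT_TRAIT_ROWS: tuple[tuple[str, str, str], ...] = (
    ("A2", "branching", _gp(_BI)),
    ("TRIA", "branching", _gp(_TRI)),
    ("TETRA", "branching", _gp(_TETRA)),
    ("LB", "degree of branching", _gp(_MONO + _BI)),
    ("HB", "degree of branching", _gp(_TRI) + "+" + _gp(_TETRA)),
    ("G0", "galactosylation", _gp(_G0)),
    ("G1", "galactosylation", _gp(_G1)),
    ("G2", "galactosylation", _gp(_G2)),
    ("G3", "galactosylation", _gp(_G3)),
    ("G4", "galactosylation", _gp(_G4)),
    ("S0", "sialylation", _gp(_S0)),
    ("S1", "sialylation", _gp(_S1)),
    ("S2", "sialylation", _gp(_S2)),
    ("S3", "sialylation", _gp(_S3)),
    ("S4", "sialylation", _gp(_S4)),
    ("A2S0", "sialylation of biantennary", f"100*({_gp(_BI_S0)})/({_gp(_BI)})"),
    ("BAMS", "sialylation of biantennary", f"100*({_gp(_BI_S1)})/({_gp(_BI)})"),
    ("BADS", "sialylation of biantennary", f"100*({_gp(_BI_S2)})/({_gp(_BI)})"),
    ("CF", "fucose position", _gp(_CORE_FUC)),
    ("AF", "fucose position", _gp(_ANT_FUC)),
    ("A2F", "fucose position", f"100*({_gp(_BI_FUC)})/({_gp(_BI)})"),
)


def default_trait_table(panel=DEFAULT_PEAK_PANEL) -> TraitDefinitionTable:
    """The 21-trait convention-based default table over the 39-peak panel."""
    formulas = tuple(parse_formula(tid, fam, src, panel)
                     for tid, fam, src in DEFAULT_TRAIT_ROWS)
    return TraitDefinitionTable(formulas, panel=tuple(panel))


def compute_traits(X: GlycanPeakMatrix, defs: TraitDefinitionTable | None = None) -> DerivedTraitMatrix:
    """Evaluate every trait formula per sample.

    ``TOTAL`` in a formula resolves to the sum of all panel peaks per
    sample.  Division by a zero denominator raises :class:`FormulaError`
    naming the trait.
    """
    if defs is None:
        defs = default_trait_table(X.peak_ids)
    missing = [p for p in defs.panel if p not in X.peak_ids]
    if missing:
        raise FormulaError(f"peak matrix lacks panel peaks: {missing}")
    cols = {p: X.values[:, X.peak_ids.index(p)] for p in defs.panel}
    cols["TOTAL"] = X.values[:, [X.peak_ids.index(p) for p in defs.panel]].sum(axis=1)
    out = np.column_stack([f.evaluate(cols) for f in defs])
    return DerivedTraitMatrix(values=out, sample_ids=X.sample_ids,
                              trait_ids=defs.trait_ids, provenance=defs)
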