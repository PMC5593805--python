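"""Efficiency metrics and their population-term decomposition.

Ligand efficiency (LE) and the binding efficiency index (BEI) normalize a
molar binding property P_mol (here |ΔG| in kcal/mol, though any numeric
property may be passed) by molecular size:

    LE  = P_mol / HAC          (kcal/mol per heavy atom)
    BEI = P_mol / MW           (kcal/mol per Dalton)

The central identity implemented here factors LE into three terms,

    LE = P_mol * (1/MW) * (MW/HAC),

where 1/MW is a *population* term — the number of moles (hence, scaled by
Avogadro's number, molecules) in a fixed 1 g sample — and MW/HAC is a
near-constant rescaling factor for drug-like ligands.  BEI is numerically
identical to the property per gram, P_gram = P_mol/MW, because the weight
of one mole in grams equals the single-molecule weight in Daltons.  The
hyperbolic decrease of LE/BEI with size is therefore a mathematical
consequence of weight normalization, not a chemical effect.

Sign convention: binding ΔG is stored as a magnitude, so efficiencies are
non-negative; readers negate negative inputs (see :mod:`ligeff.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

#: Avogadro constant (2019 SI exact value), molecules per mole.
AVOGADRO = 6.02214076e23


def ligand_efficiency(p_mol: float, hac: int) -> float:
    """LE: molar property per heavy atom, ``p_mol / hac``."""
    if hac < 1:
        raise ValueError(f"heavy atom count must be >= 1, got {hac}")
    if not math.isfinite(p_mol):
        raise ValueError(f"non-finite property value {p_mol!r}")
    return p_mol / hac


def binding_efficiency_index(p_mol: float, mw_da: float) -> float:
    """BEI: molar property per Dalton, ``p_mol / mw_da``."""
    if mw_da <= 0:
        raise ValueError(f"molecular weight must be > 0 Da, got {mw_da}")
    return p_mol / mw_da


def p_gram(p_mol: float, mw_da: float) -> float:
    """Property per gram of substance: P_gram = P_mol / MW.

    Numerically identical to :func:`binding_efficiency_index`; exposed
    separately because the two readings differ in kind — BEI is usually
    presented as a per-fragment descriptor of a single molecule, while
    P_gram is a measurable property of a weighed 1 g sample (kcal/g when
    P_mol is kcal/mol).
    """
    if mw_da <= 0:
        raise ValueError(f"molecular weight must be > 0 Da, got {mw_da}")
    return p_mol / mw_da


def molecules_per_gram(mw_da: float) -> float:
    """Number of molecules in a 1 g sample: N_A / MW.

    This is the population behind the 1/MW term — a fixed-weight sample of
    a heavier compound simply contains fewer molecules available for
    ligand-receptor pairing.
    """
    if mw_da <= 0:
        raise ValueError(f"molecular weight must be > 0 Da, got {mw_da}")
    return AVOGADRO / mw_da


def da_to_g_per_mol(mw_da: float) -> float:
    """Relabel a single-molecule weight (Da) as a molar weight (g/mol).

    The numeric value is unchanged — MW (Da) * N_A = MW (g/mol) — which is
    exactly why per-gram properties can be computed without ever writing
    N_A.  The function exists to make the descriptor-vs-property switch
    explicit in code and reports.
    """
    if mw_da <= 0:
        raise ValueError(f"molecular weight must be > 0 Da, got {mw_da}")
    return mw_da


@dataclass(frozen=True)
class EfficiencyResult:
    """LE, BEI and the three decomposition factors for one record.

    Satisfies ``le == term_pmol * term_inv_mw * term_mw_per_hac`` and
    ``bei == term_pmol * term_inv_mw`` to floating-point accuracy.
    """

    le: float
    bei: float
    term_pmol: float
    term_inv_mw: float  # 1/Da, the population term
    term_mw_per_hac: float  # Da per heavy atom, the rescaling factor


def decompose_efficiency(p_mol: float, mw_da: float, hac: int) -> EfficiencyResult:
    """Factor LE into molar property x population x rescaling terms."""
    bei = binding_efficiency_index(p_mol, mw_da)
    le = ligand_efficiency(p_mol, hac)
    return EfficiencyResult(
        le=le,
        bei=bei,
        term_pmol=p_mol,
        term_inv_mw=1.0 / mw_da,
        term_mw_per_hac=mw_da / hac,
    )


def augment_metrics(df: pd.DataFrame, p_col: str = "p_mol") -> pd.DataFrame:
    """Append metric columns to a binding table.

    Requires columns ``mw``, ``hac`` and *p_col*; adds ``le``, ``bei``,
    ``term_pmol``, ``term_inv_mw``, ``term_mw_per_hac``, ``p_gram`` and
    ``molecules_per_gram``.  Rows are assumed pre-validated (mw > 0,
    hac >= 1); vectorized for catalog-scale tables.
    """
    missing = [c for c in (p_col, "mw", "hac") if c not in df.columns]
    if missing:
        raise KeyError(f"missing required columns: {missing}")
    out = df.copy()
    out["term_pmol"] = out[p_col].astype(float)
    out["term_inv_mw"] = 1.0 / out["mw"].astype(float)
    out["term_mw_per_hac"] = out["mw"].astype(float) / out["hac"].astype(float)
    out["bei"] = out["term_pmol"] * out["term_inv_mw"]
    out["le"] = out["bei"] * out["term_mw_per_hac"]
    out["p_gram"] = out["bei"]
    out["molecules_per_gram"] = AVOGADRO * out["term_inv_mw"]
    return out
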