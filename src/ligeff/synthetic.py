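"""Synthetic binding tables and priced catalogs.

The generators emulate the statistical structure the trend analyses assume,
so the whole pipeline is testable without any external download:

* a ligand binding set whose |ΔG| magnitudes are nearly MW-independent
  (mean 8 kcal/mol), so BEI tracks c/MW, and whose MW-vs-HAC relation is
  close to linear, as for drug-like ligands;
* a building-block catalog whose weight prices sit on horizontal tiers
  ($/g independent of MW within a tier), so molar price grows linearly
  with MW band by band, with a bromine-count mixture that produces the
  k/AC hyperbola families of the Br/AC ratio descriptor.

Every record carries a molecular formula, and the MW column is always
derived from it via :func:`ligeff.moltable.compute_mw` — there is no
free-floating MW column to drift from the composition.  All randomness
flows through one seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masses import atomic_mass
from .moltable import ElementCounts, compute_ac, compute_hac, compute_mw, format_formula

_M_H = atomic_mass("H")
_M_BR = atomic_mass("Br")

#: Probability that a non-bromine heavy atom is O (and, of the rest, N);
#: roughly the heteroatom load of drug-like organic molecules.
_HETERO_P = 0.12


@dataclass(frozen=True)
class BindingGenConfig:
    """Conditions for the synthetic ligand binding set.

    Defaults mirror the study conditions of the binding analysis: 102
    ligands over 14 target classes, |ΔG| centered at 8 kcal/mol (the
    reference hyperbola coefficient), drug-like MW between 200 and 600 Da
    with MW ≈ 13.5·HAC.
    """

    n_ligands: int = 102
    n_classes: int = 14
    mw_range: tuple[float, float] = (200.0, 600.0)
    dg_mean: float = 8.0
    dg_sd: float = 1.5
    class_offset_sd: float = 0.5
    mw_hac_slope: float = 13.5
    mw_hac_noise_sd: float = 0.8  # in heavy-atom-equivalents of MW scatter
    seed: int = 0

    def validate(self) -> None:
        if self.n_ligands < 1 or self.n_classes < 1:
            raise ValueError("n_ligands and n_classes must be >= 1")
        if self.n_classes > self.n_ligands:
            raise ValueError("more target classes than ligands")
        lo, hi = self.mw_range
        if not (0 < lo < hi):
            raise ValueError(f"invalid mw_range {self.mw_range}")
        if min(self.dg_sd, self.class_offset_sd, self.mw_hac_noise_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.mw_hac_slope <= _M_H:
            raise ValueError("mw_hac_slope must exceed the hydrogen mass")


@dataclass(frozen=True)
class PriceGenConfig:
    """Conditions for the synthetic priced catalog.

    ``tiers`` is a list of (weight price in $/g, proportion) pairs with
    proportions summing to 1; within a tier the weight price is flat in MW
    up to multiplicative noise.  ``br_mixture`` maps bromine count (0-3)
    to its probability.  ``low_mw_premium``, off by default, multiplies
    the weight price below a MW threshold to mimic the price bump small
    building blocks show at the bottom of the MW range.
    """

    n_compounds: int = 50_000
    tiers: tuple[tuple[float, float], ...] = ((2.0, 1.0),)
    mw_range: tuple[float, float] = (100.0, 500.0)
    br_mixture: dict[int, float] = field(
        default_factory=lambda: {0: 0.70, 1: 0.20, 2: 0.08, 3: 0.02}
    )
    price_noise_sd: float = 0.1
    low_mw_premium: tuple[float, float] | None = None  # (threshold Da, multiplier)
    seed: int = 0

    def validate(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        if not self.tiers:
            raise ValueError("at least one price tier is required")
        prices, props = zip(*self.tiers)
        if any(p < 0 for p in prices):
            raise ValueError("tier prices must be >= 0")
        if any(w < 0 for w in props) or abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("tier proportions must be >= 0 and sum to 1")
        if not self.br_mixture or any(k < 0 for k in self.br_mixture):
            raise ValueError("invalid bromine-count mixture")
        if abs(sum(self.br_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("bromine-count probabilities must sum to 1")
        lo, hi = self.mw_range
        if not (0 < lo < hi):
            raise ValueError(f"invalid mw_range {self.mw_range}")
        if self.price_noise_sd < 0:
            raise ValueError("price_noise_sd must be >= 0")


def _split_heavy(rng: np.random.Generator, n_heavy: int) -> tuple[int, int, int]:
    """Partition non-Br heavy atoms into (C, N, O), keeping >= 1 carbon."""
    n_o = int(rng.binomial(n_heavy, _HETERO_P))
    n_o = min(n_o, n_heavy - 1)
    n_n = int(rng.binomial(n_heavy - n_o, _HETERO_P)) if n_heavy - n_o > 1 else 0
    n_n = min(n_n, n_heavy - n_o - 1)
    return n_heavy - n_o - n_n, n_n, n_o


def _counts_from_target(
    rng: np.random.Generator, n_heavy: int, target_mw: float, n_br: int = 0
) -> ElementCounts:
    """C/H/N/O(/Br) composition with *n_heavy* non-Br heavy atoms whose MW
    approximates *target_mw*; hydrogens absorb the remainder."""
    n_c, n_n, n_o = _split_heavy(rng, n_heavy)
    heavy_mw = (
        n_c * atomic_mass("C") + n_n * atomic_mass("N") + n_o * atomic_mass("O")
        + n_br * _M_BR
    )
    n_h = max(0, int(round((target_mw - heavy_mw) / _M_H)))
    counts: ElementCounts = {"C": n_c}
    if n_h:
        counts["H"] = n_h
    if n_n:
        counts["N"] = n_n
    if n_o:
        counts["O"] = n_o
    if n_br:
        counts["Br"] = n_br
    return counts


def generate_binding_dataset(config: BindingGenConfig) -> pd.DataFrame:
    """Draw a synthetic ligand binding table.

    HAC is uniform over the drug-like range implied by ``mw_range`` and
    ``mw_hac_slope``; the composition is then built so that
    MW ≈ slope·(HAC + N(0, mw_hac_noise_sd)).  |ΔG| = dg_mean + class
    offset + N(0, dg_sd), truncated at 0; realized class offsets are
    centered so the global mean stays exactly dg_mean before truncation.

    Returns a frame with columns ``id, formula, mw, hac, ac, p_mol,
    target_class``; deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_ligands
    lo, hi = config.mw_range
    hac_lo = max(2, int(np.ceil(lo / config.mw_hac_slope)))
    hac_hi = max(hac_lo, int(np.floor(hi / config.mw_hac_slope)))

    hacs = rng.integers(hac_lo, hac_hi + 1, size=n)
    mw_noise = rng.normal(0.0, config.mw_hac_noise_sd, size=n)

    # round-robin class deal + shuffle guarantees every class is populated
    labels = np.array([f"T{i % config.n_classes + 1:02d}" for i in range(n)])
    rng.shuffle(labels)
    class_names = [f"T{i + 1:02d}" for i in range(config.n_classes)]
    offsets = dict(zip(class_names, rng.normal(0.0, config.class_offset_sd,
                                               size=config.n_classes)))
    per_record_offset = np.array([offsets[c] for c in labels])
    if n > 0:
        per_record_offset -= per_record_offset.mean()

    dg = config.dg_mean + per_record_offset + rng.normal(0.0, config.dg_sd, size=n)
    dg = np.maximum(dg, 0.0)

    rows = []
    for i in range(n):
        h = int(hacs[i])
        target = config.mw_hac_slope * (h + mw_noise[i])
        counts = _counts_from_target(rng, h, target)
        rows.append(
            {
                "id": f"LIG{i + 1:04d}",
                "formula": format_formula(counts),
                "mw": compute_mw(counts),
                "hac": compute_hac(counts),
                "ac": compute_ac(counts),
                "p_mol": float(dg[i]),
                "target_class": labels[i],
            }
        )
    return pd.DataFrame(rows)


def generate_price_catalog(config: PriceGenConfig) -> pd.DataFrame:
    """Draw a synthetic priced building-block catalog.

    Each compound gets a price tier, a bromine count from the mixture, and
    a C/H/N/O/Br composition targeting a uniform MW in ``mw_range``; the
    weight price is tier·(1 + N(0, price_noise_sd)) (floored at 1% of the
    tier price), times the low-MW premium when configured, and the molar
    price is weight price · MW.

    Returns columns ``id, formula, mw, hac, ac, brc, tier_price,
    price_per_g, price_per_mol``; deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_compounds
    prices, props = map(np.asarray, zip(*config.tiers))
    tier_idx = rng.choice(len(prices), size=n, p=props / props.sum())
    br_counts, br_probs = map(np.asarray, zip(*sorted(config.br_mixture.items())))
    n_br = rng.choice(br_counts, size=n, p=br_probs / br_probs.sum())
    lo, hi = config.mw_range
    target_mw = rng.uniform(lo, hi, size=n)
    noise = rng.normal(0.0, config.price_noise_sd, size=n)

    rows = []
    for i in range(n):
        k = int(n_br[i])
        # leave room for at least one carbon and a few hydrogens
        tmw = max(target_mw[i], k * _M_BR + 20.0)
        n_heavy = max(1, int(round((tmw - k * _M_BR) / 13.5)))
        counts = _counts_from_target(rng, n_heavy, tmw, n_br=k)
        mw = compute_mw(counts)
        tier_price = float(prices[tier_idx[i]])
        price_g = tier_price * max(1.0 + noise[i], 0.01)
        if config.low_mw_premium is not None:
            threshold, multiplier = config.low_mw_premium
            if mw < threshold:
                price_g *= multiplier
        rows.append(
            {
                "id": f"CMP{i + 1:07d}",
                "formula": format_formula(counts),
                "mw": mw,
                "hac": compute_hac(counts),
                "ac": compute_ac(counts),
                "brc": k,
                "tier_price": tier_price,
                "price_per_g": price_g,
                "price_per_mol": price_g * mw,
            }
        )
    return pd.DataFrame(rows)


def dedupe_catalog(
    records: pd.DataFrame,
    key_cols: tuple[str, ...] = ("formula", "price_per_g"),
) -> tuple[pd.DataFrame, int]:
    """Drop duplicate catalog notations; returns (deduped, removed count).

    The duplicate key is the molecular formula together with the exact
    weight price — a conservative notion of "the same notation" that never
    merges genuinely different offers.  Idempotent; keeps first occurrence.
    """
    missing = [c for c in key_cols if c not in records.columns]
    if missing:
        raise KeyError(f"missing dedupe key columns: {missing}")
    deduped = records.drop_duplicates(subset=list(key_cols), keep="first")
    return deduped.reset_index(drop=True), int(len(records) - len(deduped))
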