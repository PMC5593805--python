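"""Trend analyses: reference hyperbolas, MW-binned statistics, linear fits.

Two report pipelines mirror the two empirical analyses the metrics motivate:

* :func:`run_binding_analysis` — efficiency-vs-size panels for a ligand
  binding table: BEI vs MW and LE vs HAC, each overlaid with the unfitted
  reference hyperbola c/x (default c = 8 kcal/mol), plus the MW-vs-HAC
  linearity check and the raw property-vs-MW scatter.
* :func:`run_economy_analysis` — structure-economy panels for a priced
  compound catalog: weight price ($/g, the market's native efficiency-type
  scale) and molar price ($/mol = $/g * MW) against MW, raw and binned,
  plus ratio-descriptor panels (MW/HAC vs HAC, Br/AC vs AC, BrC vs MW).

All analysis surfaces are tables; plotting is a thin optional side output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import augment_metrics

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# models


@dataclass(frozen=True)
class HyperbolaModel:
    """The curve c/x; ``fitted=False`` marks an unoptimized reference."""

    c: float
    x_variable: str = "MW"
    fitted: bool = False

    def predict(self, xs) -> np.ndarray:
        return reference_hyperbola(self.c, xs) if self.c > 0 else np.zeros(len(xs))


@dataclass(frozen=True)
class LinearTrend:
    """Ordinary least-squares line with slope significance."""

    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float = float("nan")

    @property
    def t_value(self) -> float:
        """t statistic for slope = 0; nan when the stderr is degenerate."""
        if not self.slope_stderr or math.isnan(self.slope_stderr):
            return float("nan")
        return self.slope / self.slope_stderr


@dataclass(frozen=True)
class BinnedStat:
    """Per-MW-bin count/mean/sd of a value column.

    Bins are half-open ``[lo + k*w, lo + (k+1)*w)``.  Empty bins are kept
    with count 0 and NaN mean; single-record bins carry a NaN sd.  Records
    outside the range are excluded and counted in ``n_below``/``n_above``,
    never silently dropped.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    n_below: int = 0
    n_above: int = 0

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def weighted_mean(self) -> float:
        """Count-weighted mean of bin means == global in-range mean."""
        n = self.counts.sum()
        if n == 0:
            return float("nan")
        occupied = self.counts > 0
        return float(np.sum(self.counts[occupied] * self.means[occupied]) / n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "bin_center": self.centers,
                "count": self.counts,
                "mean": self.means,
                "sd": self.sds,
            }
        )


# ---------------------------------------------------------------------------
# elementary operations


def reference_hyperbola(c: float, xs) -> np.ndarray:
    """Evaluate the reference curve c/x element-wise; all x must be > 0."""
    if c <= 0:
        raise ValueError(f"hyperbola coefficient must be > 0, got {c}")
    xs = np.asarray(xs, dtype=float)
    bad = np.flatnonzero(xs <= 0)
    if bad.size:
        raise ValueError(f"non-positive x at index {bad[0]}: {xs[bad[0]]}")
    return c / xs


def fit_hyperbola_coefficient(xs, ys, x_variable: str = "MW") -> HyperbolaModel:
    """Least-squares c for y = c/x, closed form c = Σ(y/x) / Σ(1/x²).

    The analyses overlay an unfitted reference curve; the fitted
    coefficient is reported alongside it so the overlay is checkable
    against data rather than eyeballed.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or xs.size != ys.size:
        raise ValueError("xs and ys must be equal-length and non-empty")
    if np.any(xs <= 0):
        raise ValueError("all xs must be > 0")
    c = float(np.sum(ys / xs) / np.sum(1.0 / xs**2))
    return HyperbolaModel(c=c, x_variable=x_variable, fitted=True)


def binned_means(
    df: pd.DataFrame,
    value_col: str,
    key_col: str = "mw",
    bin_width: float = 50.0,
    lo: float = 0.0,
    hi: float = 1000.0,
) -> BinnedStat:
    """Per-bin count/mean/sd of *value_col* keyed by *key_col*."""
    if bin_width <= 0:
        raise ValueError(f"bin width must be > 0, got {bin_width}")
    if lo >= hi:
        raise ValueError(f"invalid range [{lo}, {hi})")
    n_bins = int(math.ceil((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    keys = df[key_col].to_numpy(dtype=float)
    values = df[value_col].to_numpy(dtype=float)
    n_below = int(np.sum(keys < lo))
    n_above = int(np.sum(keys >= edges[-1]))
    in_range = (keys >= lo) & (keys < edges[-1])
    idx = np.floor((keys[in_range] - lo) / bin_width).astype(int)
    v = values[in_range]
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=v, minlength=n_bins)
    means = np.full(n_bins, np.nan)
    occupied = counts > 0
    means[occupied] = sums[occupied] / counts[occupied]
    sq = np.bincount(idx, weights=(v - means[idx]) ** 2, minlength=n_bins)
    sds = np.full(n_bins, np.nan)
    multi = counts > 1
    sds[multi] = np.sqrt(sq[multi] / (counts[multi] - 1))
    return BinnedStat(
        bin_edges=edges, counts=counts, means=means, sds=sds,
        n_below=n_below, n_above=n_above,
    )


def linear_trend(xs, ys, weights=None) -> LinearTrend:
    """Least-squares line fit; constant ys yield slope 0 with r² flagged 0.

    With *weights* (e.g. bin counts when fitting binned means, since the
    variance of a bin mean scales as 1/count) the fit is weighted least
    squares; otherwise ordinary least squares.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 2 or xs.size != ys.size:
        raise ValueError("need >= 2 paired points")
    if np.all(xs == xs[0]):
        raise ValueError("degenerate fit: all x values identical")
    if np.all(ys == ys[0]):
        return LinearTrend(slope=0.0, intercept=float(ys[0]), r_squared=0.0,
                           slope_stderr=0.0)
    if weights is None:
        res = stats.linregress(xs, ys)
        return LinearTrend(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue**2),
            slope_stderr=float(res.stderr),
        )
    import statsmodels.api as sm

    fit = sm.WLS(ys, sm.add_constant(xs), weights=np.asarray(weights, float)).fit()
    return LinearTrend(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        slope_stderr=float(fit.bse[1]),
    )


def weight_to_molar_price(price_per_g: float, mw_da: float) -> float:
    """$/g -> $/mol: multiply by the molar weight (numerically MW in Da)."""
    if mw_da <= 0:
        raise ValueError(f"molecular weight must be > 0 Da, got {mw_da}")
    if price_per_g < 0:
        raise ValueError(f"negative weight price {price_per_g}")
    return price_per_g * mw_da


# ---------------------------------------------------------------------------
# report pipelines


@dataclass(frozen=True)
class TrendConfig:
    """Shared knobs for the report pipelines.

    ``ref_c`` is the unoptimized overlay coefficient (kcal/mol for binding
    data); ``bin_width``/``mw_range`` define the half-open MW bins used by
    the binned-statistics panels.
    """

    ref_c: float = 8.0
    bin_width: float = 50.0
    mw_range: tuple[float, float] = (0.0, 1000.0)


@dataclass
class AnalysisReport:
    """Panel tables plus a JSON-serializable summary."""

    tables: dict[str, pd.DataFrame]
    summary: dict = field(default_factory=dict)


def _drop_invalid(df: pd.DataFrame, checks: dict[str, str]) -> tuple[pd.DataFrame, dict]:
    """Exclude rows failing per-column validity predicates, with counts."""
    mask = pd.Series(True, index=df.index)
    excluded: dict[str, int] = {}
    for col, rule in checks.items():
        if col not in df.columns:
            raise KeyError(f"missing required column {col!r}")
        vals = pd.to_numeric(df[col], errors="coerce")
        if rule == "positive":
            ok = vals.notna() & (vals > 0)
        elif rule == "nonnegative":
            ok = vals.notna() & (vals >= 0)
        else:  # finite
            ok = vals.notna()
        n_bad = int((~ok & mask).sum())
        if n_bad:
            excluded[col] = n_bad
            logger.info("excluding %d rows with invalid %s", n_bad, col)
        mask &= ok
    return df.loc[mask].copy(), excluded


def run_binding_analysis(
    records: pd.DataFrame,
    config: TrendConfig = TrendConfig(),
    p_col: str = "p_mol",
) -> AnalysisReport:
    """Efficiency-vs-size report for a ligand binding table.

    Emits four panel tables — BEI vs MW with the c/MW overlay, MW vs HAC
    together with MW/HAC vs HAC, LE vs HAC with the c/HAC overlay, and the
    raw property vs MW — plus fitted hyperbola coefficients, the MW-vs-HAC
    line and per-target-class mean signed residuals from the reference
    curve.
    """
    if len(records) < 2:
        raise ValueError("binding analysis needs at least 2 records")
    df, excluded = _drop_invalid(
        records, {p_col: "nonnegative", "mw": "positive", "hac": "positive"}
    )
    if len(df) < 2:
        raise ValueError("fewer than 2 valid records after exclusions")
    df = augment_metrics(df, p_col=p_col)
    has_class = "target_class" in df.columns
    if not has_class:
        df["target_class"] = "all"

    ref_bei = reference_hyperbola(config.ref_c, df["mw"])
    ref_le = reference_hyperbola(config.ref_c, df["hac"])
    id_cols = [c for c in ("id",) if c in df.columns]

    tables = {
        "fig2a": pd.concat(
            [df[id_cols + ["target_class", "mw", "bei"]],
             pd.Series(ref_bei, index=df.index, name="ref_bei")], axis=1),
        "fig2b": df[id_cols + ["hac", "mw", "term_mw_per_hac"]].rename(
            columns={"term_mw_per_hac": "mw_per_hac"}),
        "fig2c": pd.concat(
            [df[id_cols + ["target_class", "hac", "le"]],
             pd.Series(ref_le, index=df.index, name="ref_le")], axis=1),
        "fig2d": df[id_cols + ["mw", p_col]],
    }

    c_bei = fit_hyperbola_coefficient(df["mw"], df["bei"], "MW")
    c_le = fit_hyperbola_coefficient(df["hac"], df["le"], "HAC")
    mw_hac_line = linear_trend(df["hac"], df["mw"])
    resid = df["bei"] - ref_bei
    class_resid = resid.groupby(df["target_class"]).mean().to_dict()

    summary = {
        "n_in": int(len(records)),
        "n_excluded": excluded,
        "n_used": int(len(df)),
        "ref_c": config.ref_c,
        "fitted_c_bei": c_bei.c,
        "fitted_c_le": c_le.c,
        "mw_vs_hac": {
            "slope": mw_hac_line.slope,
            "intercept": mw_hac_line.intercept,
            "r_squared": mw_hac_line.r_squared,
        },
        "class_mean_bei_residual": {str(k): float(v) for k, v in class_resid.items()},
    }
    return AnalysisReport(tables=tables, summary=summary)


def run_economy_analysis(
    records: pd.DataFrame,
    config: TrendConfig = TrendConfig(),
) -> AnalysisReport:
    """Structure-economy report for a priced catalog.

    Requires ``mw`` and ``price_per_g``; derives ``price_per_mol`` when
    absent.  Ratio-descriptor panels use ``hac``/``ac``/``brc`` columns
    when present.
    """
    if len(records) < 2:
        raise ValueError("economy analysis needs at least 2 priced records")
    df, excluded = _drop_invalid(
        records, {"mw": "positive", "price_per_g": "nonnegative"}
    )
    if len(df) < 2:
        raise ValueError("fewer than 2 valid records after exclusions")
    if "price_per_mol" not in df.columns:
        df["price_per_mol"] = df["price_per_g"] * df["mw"]

    lo, hi = config.mw_range
    gram_bins = binned_means(df, "price_per_g", "mw", config.bin_width, lo, hi)
    molar_bins = binned_means(df, "price_per_mol", "mw", config.bin_width, lo, hi)

    id_cols = [c for c in ("id",) if c in df.columns]
    tables = {
        "fig3a": df[id_cols + ["mw", "price_per_g"]],
        "fig3b": gram_bins.to_frame(),
        "fig3c": df[id_cols + ["mw", "price_per_mol"]],
        "fig3d": molar_bins.to_frame(),
    }
    if {"hac"}.issubset(df.columns):
        panel = df[id_cols + ["hac", "mw"]].copy()
        panel["mw_per_hac"] = df["mw"] / df["hac"]
        tables["fig3e"] = panel
    if {"ac", "brc"}.issubset(df.columns):
        panel = df[id_cols + ["ac", "brc"]].copy()
        panel["br_per_ac"] = df["brc"] / df["ac"]
        tables["fig3f"] = panel
        tables["fig3g"] = df[id_cols + ["mw", "brc"]]

    def _bin_fit(bins: BinnedStat) -> LinearTrend:
        # count-weighted: a bin mean's variance scales as 1/count, so
        # sparse edge bins must not dominate the trend
        ok = bins.counts > 0
        return linear_trend(bins.centers[ok], bins.means[ok],
                            weights=bins.counts[ok])

    gram_fit = _bin_fit(gram_bins)
    molar_fit = _bin_fit(molar_bins)

    summary = {
        "n_in": int(len(records)),
        "n_excluded": excluded,
        "n_used": int(len(df)),
        "bin_width": config.bin_width,
        "mw_range": list(config.mw_range),
        "binned_out_of_range": {"below": gram_bins.n_below, "above": gram_bins.n_above},
        "binned_gram_price": {
            "slope": gram_fit.slope,
            "t_value": gram_fit.t_value,
            "r_squared": gram_fit.r_squared,
            "global_mean": gram_bins.weighted_mean(),
        },
        "binned_molar_price": {
            "slope": molar_fit.slope,
            "intercept": molar_fit.intercept,
            "r_squared": molar_fit.r_squared,
        },
    }
    return AnalysisReport(tables=tables, summary=summary)
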