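"""Genome-scan outputs: threshold sweeps, LOESS profiles, sister diagnostic.

``threshold_sweep`` recomputes, for each minor-allele-count threshold n,
the number of retained SNPs and the mean clipped F_ST (per RAD site after
aggregation by default).  ``loess_profile`` smooths per-site F_ST along a
chromosome with a locally weighted quadratic regression (tricube weights,
span expressed as a fraction of the records, no robustness reweighting) —
the same smoother as R's ``loess`` with ``degree = 2``, ``span = 0.4`` and
``surface = "direct"``.  ``sister_correlation`` reports, per threshold, the
Pearson correlation of aggregated F_ST between the two RAD sites flanking
the same restriction cut: tightly linked markers should tell the same
story, so the correlation rising under filtering is the empirical guide
for choosing n.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fst import FstRecord

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# threshold sweep
# ---------------------------------------------------------------------------

def records_frame(records: Sequence[FstRecord]) -> pd.DataFrame:
    """Per-position records as a DataFrame (clipped values in ``fst``)."""
    return pd.DataFrame(
        {
            "site_id": [r.site_id for r in records],
            "chromosome": [r.chromosome for r in records],
            "position": [r.position for r in records],
            "estimator": [r.estimator for r in records],
            "minor_allele_count": [r.minor_allele_count for r in records],
            "fst_raw": [r.fst_raw for r in records],
            "fst": [r.fst for r in records],
        }
    )


def _aggregate_frame(
    df: pd.DataFrame, aggregation: str, rng: np.random.Generator | None
) -> pd.DataFrame:
    """Per-site aggregation of clipped per-position values.

    For ``max`` the retained row is the SNP attaining the maximum (leftmost
    on ties), so its position anchors the site in profiles.
    """
    if aggregation == "max":
        ordered = df.sort_values(
            ["site_id", "fst", "position"], ascending=[True, False, True]
        )
        return ordered.drop_duplicates("site_id", keep="first").reset_index(drop=True)
    if aggregation == "mean":
        ordered = df.sort_values(["site_id", "position"])
        out = ordered.drop_duplicates("site_id", keep="first").reset_index(drop=True).copy()
        g = ordered.groupby("site_id")
        out["fst"] = g["fst"].mean().loc[out["site_id"]].to_numpy()
        out["minor_allele_count"] = (
            g["minor_allele_count"].min().loc[out["site_id"]].to_numpy()
        )
        return out
    if aggregation == "random":
        if rng is None:
            raise ValueError("random aggregation requires an rng")
        ordered = df.sort_values(["site_id", "position"]).reset_index(drop=True)
        idx = [
            grp.index[int(rng.integers(len(grp)))]
            for _, grp in ordered.groupby("site_id", sort=True)
        ]
        return ordered.loc[idx].reset_index(drop=True)
    raise ValueError(f"unknown aggregation {aggregation!r}")


def site_table(
    records: Sequence[FstRecord] | pd.DataFrame,
    n_min_minor: int = 1,
    aggregation: str = "max",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-RAD-site aggregated F_ST at one minor-allele-count threshold.

    Positions failing the threshold are removed *before* aggregation, so a
    site's value at threshold n uses only positions passing n.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    df = df[df["minor_allele_count"] >= n_min_minor]
    if df.empty:
        return df
    return _aggregate_frame(df, aggregation, rng)


def threshold_sweep(
    records: Sequence[FstRecord] | pd.DataFrame,
    n_range: Iterable[int] = range(1, 11),
    aggregation: str = "max",
    per_site: bool = True,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """SNP counts and mean F_ST for a series of minor-allele thresholds.

    Returns one row per n with ``snp_count`` (variable positions passing
    the threshold) and ``mean_fst`` (mean clipped F_ST over per-site
    aggregated values by default, or over individual SNPs with
    ``per_site=False``); the mean is missing (NaN) when nothing passes.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    rows = []
    for n in n_range:
        sub = df[df["minor_allele_count"] >= n]
        count = int(len(sub))
        if count == 0:
            mean = float("nan")
        elif per_site:
            mean = float(_aggregate_frame(sub, aggregation, rng)["fst"].mean())
        else:
            mean = float(sub["fst"].mean())
        rows.append({"n": int(n), "snp_count": count, "mean_fst": mean})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LOESS profile
# ---------------------------------------------------------------------------

@dataclass
class ScanProfile:
    """Smoothed differentiation profile along one chromosome."""

    chromosome: str
    eval_positions: np.ndarray
    smoothed_fst: np.ndarray
    span: float = 0.4
    degree: int = 2

    def __post_init__(self) -> None:
        self.eval_positions = np.asarray(self.eval_positions, dtype=np.int64)
        self.smoothed_fst = np.asarray(self.smoothed_fst, dtype=float)
        if np.any(np.diff(self.eval_positions) <= 0):
            raise ValueError("eval_positions must be strictly increasing")
        if not np.all(np.isfinite(self.smoothed_fst)):
            raise ValueError("smoothed values must be finite")


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    eval_x: np.ndarray,
    span: float = 0.4,
    degree: int = 2,
    _block: int = 512,
) -> np.ndarray:
    """Locally weighted polynomial regression with tricube weights.

    The neighbourhood of each evaluation point consists of the
    ``floor(span * n)`` records nearest by position (all of them, with the
    bandwidth inflated by ``span``, when span > 1); weights are tricube in
    the distance scaled by the neighbourhood radius; a weighted polynomial
    of the requested degree is fitted and evaluated at the point.  No
    robustness reweighting iterations are performed.  When fewer records
    than a degree-d fit needs are available the degree is lowered with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    eval_x = np.asarray(eval_x, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("no records to smooth")
    if n < degree + 2:
        new_degree = max(n - 2, 0)
        log.warning(
            "only %d records: lowering LOESS degree from %d to %d", n, degree, new_degree
        )
        degree = new_degree
    if span <= 1.0:
        q = int(span * n + 1e-9)
    else:
        q = n
    q = min(max(q, degree + 1), n)

    out = np.empty(len(eval_x))
    for lo in range(0, len(eval_x), _block):
        ex = eval_x[lo : lo + _block]
        d = np.abs(ex[:, None] - x[None, :])
        h = np.partition(d, q - 1, axis=1)[:, q - 1]
        if span > 1.0:
            h = h * span
        h = np.where(h > 0, h, 1.0)  # degenerate: all neighbours coincide
        u = d / h[:, None]
        w = np.clip(1.0 - u**3, 0.0, None) ** 3
        z = (x[None, :] - ex[:, None]) / h[:, None]
        # weighted normal equations, one (degree+1)^2 system per eval point
        powers = np.stack([z**k for k in range(degree + 1)], axis=-1)
        wp = w[:, :, None] * powers
        M = np.einsum("eij,eik->ejk", wp, powers)
        v = np.einsum("eij,ei->ej", wp, y[None, :])
        try:
            coef = np.linalg.solve(M, v[..., None])[..., 0]
        except np.linalg.LinAlgError:
            coef = np.einsum("ejk,ek->ej", np.linalg.pinv(M), v)
        out[lo : lo + _block] = coef[:, 0]  # value at z = 0
    return out


def loess_profile(
    records: Sequence[FstRecord] | pd.DataFrame,
    chromosome: str | None = None,
    span: float = 0.4,
    degree: int = 2,
    grid_step: int = 1000,
    eval_positions: np.ndarray | None = None,
) -> ScanProfile:
    """Smoothed F_ST profile of one chromosome from per-site records.

    Profiles are fitted per chromosome, never across chromosome boundaries;
    evaluation points default to the record positions plus a uniform grid
    of ``grid_step`` bp for plotting.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    if chromosome is not None:
        df = df[df["chromosome"] == chromosome]
    else:
        chroms = df["chromosome"].unique()
        if len(chroms) != 1:
            raise ValueError(
                f"records span chromosomes {list(chroms)}; pass chromosome="
            )
        chromosome = str(chroms[0])
    if df.empty:
        raise ValueError(f"no records on chromosome {chromosome!r}")
    x = df["position"].to_numpy(dtype=float)
    y = df["fst"].to_numpy(dtype=float)
    if eval_positions is None:
        grid = np.arange(x.min(), x.max() + 1, grid_step)
        eval_positions = np.unique(np.concatenate([x, grid]).astype(np.int64))
    else:
        eval_positions = np.unique(np.asarray(eval_positions, dtype=np.int64))
    smoothed = loess_smooth(x, y, eval_positions.astype(float), span=span, degree=degree)
    return ScanProfile(
        chromosome=chromosome,
        eval_positions=eval_positions,
        smoothed_fst=smoothed,
        span=span,
        degree=degree,
    )


# ---------------------------------------------------------------------------
# sister-site diagnostic
# ---------------------------------------------------------------------------

def sister_correlation(
    records: pd.DataFrame,
    n_values: Iterable[int] = range(1, 11),
    aggregation: str = "max",
    min_pairs: int = 10,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pearson correlation of F_ST between sister RAD sites, per threshold.

    ``records`` holds per-position records with two extra columns:
    ``pair_id`` (shared by the two sites flanking one cut) and ``side``
    ("left"/"right").  For each n, positions failing the threshold are
    dropped, the remaining ones aggregated per site, and the correlation
    computed over pairs where both sides retain at least one passing SNP.
    With fewer than ``min_pairs`` complete pairs (or a degenerate variance)
    the correlation is reported missing.
    """
    required = {"pair_id", "side", "site_id", "minor_allele_count", "fst", "position"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records lack columns {sorted(missing)}")
    rows = []
    for n in n_values:
        sub = records[records["minor_allele_count"] >= n]
        if sub.empty:
            rows.append({"n": int(n), "pair_count": 0, "r": float("nan")})
            continue
        agg = _aggregate_frame(sub, aggregation, rng)
        wide = agg.pivot_table(
            index="pair_id", columns="side", values="fst", aggfunc="first"
        )
        if not {"left", "right"} <= set(wide.columns):
            rows.append({"n": int(n), "pair_count": 0, "r": float("nan")})
            continue
        wide = wide.dropna(subset=["left", "right"])
        count = int(len(wide))
        if count < min_pairs or wide["left"].std() == 0 or wide["right"].std() == 0:
            r = float("nan")
        else:
            r = float(stats.pearsonr(wide["left"], wide["right"]).statistic)
        rows.append({"n": int(n), "pair_count": count, "r": r})
    return pd.DataFrame(rows)
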