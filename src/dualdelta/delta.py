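"""Delta-radiomics: per-feature time slopes, the dual feature table, and
ICC reproducibility gating.

A delta feature is the slope (I_followup − I_baseline) / (t_followup −
t_baseline) in feature-units per day.  The dual table concatenates four
blocks — classic intratumoral, classic peritumoral (both from the
follow-up scan, the last pre-surgical CT), delta intratumoral and delta
peritumoral — giving 4 × 851 = 3404 columns at the default inventory.

ICC uses the two-way random-effects, absolute-agreement, single-measurement
model (ICC(2,1)): with subjects crossed with raters (or repeats),

    ICC(2,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E + k (MS_C − MS_E) / n)

from the standard two-way ANOVA mean squares.  Features pass the gate when
both the intra- and inter-observer ICC exceed the threshold (default 0.75).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .radiomics import FeatureTable, FeatureVector

__all__ = [
    "DeltaFeatureVector",
    "ICCReport",
    "delta_slope",
    "assemble_dual_table",
    "icc_2_1",
    "compute_icc",
    "icc_filter",
]

BLOCKS = ("classic_intra", "classic_peri", "delta_intra", "delta_peri")


@dataclass
class DeltaFeatureVector:
    """Named slopes (feature-units/day) for one subject and region."""

    values: dict[str, float]
    interval_days: float
    subject_id: str = ""
    region_tag: str = "intratumoral"

    def __post_init__(self):
        if self.interval_days <= 0:
            raise ValueError("interval_days must be positive")

    def __len__(self):
        return len(self.values)


def delta_slope(
    baseline: FeatureVector | dict,
    followup: FeatureVector | dict,
    t_b_days: float,
    t_f_days: float,
) -> DeltaFeatureVector:
    """Elementwise time slope (I_f − I_b) / (t_f − t_b)."""
    if t_f_days <= t_b_days:
        raise ValueError("follow-up time must be strictly after baseline")
    vb = baseline.values if isinstance(baseline, FeatureVector) else dict(baseline)
    vf = followup.values if isinstance(followup, FeatureVector) else dict(followup)
    if list(vb) != list(vf):
        raise ValueError("baseline and follow-up feature names do not match")
    dt = float(t_f_days - t_b_days)
    slopes = {k: (vf[k] - vb[k]) / dt for k in vb}
    sid = baseline.subject_id if isinstance(baseline, FeatureVector) else ""
    region = baseline.region_tag if isinstance(baseline, FeatureVector) else "intratumoral"
    return DeltaFeatureVector(slopes, interval_days=dt, subject_id=sid, region_tag=region)


def _block_frame(block, prefix: str) -> pd.DataFrame:
    if isinstance(block, FeatureTable):
        df = block.data.copy()
    elif isinstance(block, pd.DataFrame):
        df = block.copy()
    else:  # list of vectors
        rows = {v.subject_id: v.values for v in block}
        df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"{prefix}__{c}" for c in df.columns]
    return df


def assemble_dual_table(
    classic_intra, classic_peri=None, delta_intra=None, delta_peri=None
) -> FeatureTable:
    """Concatenate the four feature blocks into the dual table.

    Blocks passed as None are skipped (the classic-only or delta-only
    ablations).  All supplied blocks must cover the same subjects; column
    names gain a block prefix so the four 851-column sets stay disjoint.
    """
    blocks = {
        "classic_intra": classic_intra,
        "classic_peri": classic_peri,
        "delta_intra": delta_intra,
        "delta_peri": delta_peri,
    }
    frames = []
    index = None
    for name, block in blocks.items():
        if block is None:
            continue
        df = _block_frame(block, name)
        if index is None:
            index = df.index
        elif not index.equals(df.index):
            if set(index) != set(df.index):
                raise ValueError(f"block {name} covers different subjects")
            df = df.loc[index]
        frames.append(df)
    if not frames:
        raise ValueError("at least one block is required")
    return FeatureTable(pd.concat(frames, axis=1))


def icc_2_1(data: np.ndarray) -> float:
    """ICC(2,1) for an (n subjects × k raters) matrix via two-way ANOVA.

    Degenerate input (zero total variance) is perfect agreement by
    convention and returns 1.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 raters/repeats")
    grand = data.mean()
    if np.allclose(data, grand):
        return 1.0
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom == 0:
        return 1.0
    return float((ms_r - ms_e) / denom)


@dataclass
class ICCReport:
    """Per-feature intra- and inter-observer ICC with the pass gate."""

    data: pd.DataFrame  # columns: intra_icc, inter_icc, pass
    threshold: float = 0.75

    @property
    def passing(self) -> list[str]:
        return list(self.data.index[self.data["pass"]])


def compute_icc(
    measurements: dict[str, pd.DataFrame] | pd.DataFrame,
    mode: str = "inter",
) -> pd.Series:
    """Per-feature ICC(2,1) across raters (inter) or repeats (intra).

    ``measurements`` maps rater-or-repeat id → (subjects × features) frame,
    all sharing index and columns.  Returns a Series of ICC values.
    """
    if isinstance(measurements, pd.DataFrame):
        raise TypeError("pass a dict of rater/repeat frames")
    if mode not in ("intra", "inter"):
        raise ValueError("mode must be 'intra' or 'inter'")
    frames = list(measurements.values())
    if len(frames) < 2:
        raise ValueError(f"{mode} ICC needs >= 2 raters/repeats")
    idx, cols = frames[0].index, frames[0].columns
    stack = np.stack([f.loc[idx, cols].to_numpy(dtype=float) for f in frames], axis=2)
    out = {c: icc_2_1(stack[:, j, :]) for j, c in enumerate(cols)}
    return pd.Series(out, name=f"{mode}_icc")


def icc_report(
    intra: dict[str, pd.DataFrame] | None,
    inter: dict[str, pd.DataFrame] | None,
    threshold: float = 0.75,
) -> ICCReport:
    """Combine intra/inter ICC series into a gating report.

    A missing mode (None) is treated as passing (ICC 1), so the gate can be
    run with only repeats or only raters available.
    """
    parts = {}
    if intra is not None:
        parts["intra_icc"] = compute_icc(intra, "intra")
    if inter is not None:
        parts["inter_icc"] = compute_icc(inter, "inter")
    if not parts:
        raise ValueError("need at least one of intra/inter measurements")
    df = pd.DataFrame(parts)
    for col in ("intra_icc", "inter_icc"):
        if col not in df:
            df[col] = 1.0
    df["pass"] = (df["intra_icc"] > threshold) & (df["inter_icc"] > threshold)
    return ICCReport(df[["intra_icc", "inter_icc", "pass"]], threshold=threshold)


def icc_filter(
    table: FeatureTable | pd.DataFrame,
    report: ICCReport,
    threshold: float | None = None,
) -> FeatureTable:
    """Keep only the columns whose intra AND inter ICC exceed the threshold.

    Column order is preserved.  Fails loudly if no feature survives.
    """
    df = table.data if isinstance(table, FeatureTable) else table
    thr = report.threshold if threshold is None else threshold
    missing = [c for c in df.columns if c not in report.data.index]
    if missing:
        raise ValueError(f"ICC report does not cover columns: {missing[:5]}")
    rep = report.data.loc[list(df.columns)]
    keep = [
        c for c in df.columns
        if rep.loc[c, "intra_icc"] > thr and rep.loc[c, "inter_icc"] > thr
    ]
    if not keep:
        n = len(df.columns)
        raise ValueError(
            f"no features pass the ICC gate at threshold {thr} "
            f"(median intra {rep['intra_icc'].median():.3f}, "
            f"inter {rep['inter_icc'].median():.3f}, {n} candidates)"
        )
    return FeatureTable(df[keep].copy())
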