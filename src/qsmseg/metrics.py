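"""Agreement evaluation: Dice, volumes, susceptibilities, and cohort stats.

The Dice coefficient between a manual mask M and an automated mask A is

    D = 2 * vol(M & A) / (vol(M) + vol(A)),

computed over the whole 3D volume (both hemispheres pooled), 1 for a perfect
match and 0 for disjoint masks. Volume/susceptibility agreement across a
cohort is summarized by Pearson correlation, Bland-Altman limits of
agreement (mean difference +/- 1.96 SD), and paired t-tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import read_labels, read_volume

__all__ = [
    "dice_coefficient", "region_volume", "mean_susceptibility",
    "pearson_correlation", "bland_altman", "paired_t_test",
    "AgreementReport", "evaluate_cohort", "format_mean_sd",
    "format_bland_altman",
]


def dice_coefficient(m: np.ndarray, a: np.ndarray) -> float:
    """Volume-level Dice overlap of two binary masks on the same grid.

    Degenerate cases: both masks empty -> 1 (vacuous perfect agreement);
    exactly one empty -> 0.
    """
    m = np.asarray(m, dtype=bool)
    a = np.asarray(a, dtype=bool)
    if m.shape != a.shape:
        raise ValueError(f"mask shapes differ: {m.shape} vs {a.shape}")
    sm = int(m.sum())
    sa = int(a.sum())
    if sm + sa == 0:
        return 1.0
    return 2.0 * int((m & a).sum()) / (sm + sa)


def region_volume(mask: np.ndarray, voxel_size) -> float:
    """Voxel count times voxel volume, in mm^3."""
    return float(np.asarray(mask, dtype=bool).sum() * np.prod(voxel_size))


def mean_susceptibility(volume: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of the map (ppm) under a non-empty mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mean susceptibility of an empty region is undefined")
    return float(np.asarray(volume)[mask].mean())


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided p-value from the t distribution (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bland_altman(x, y) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement of y - x.

    Returns ``(mean_diff, loa_low, loa_high)`` with limits at
    ``mean_diff +/- 1.96 * SD`` (sample SD, ddof=1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length samples with n >= 2")
    d = y - x
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def paired_t_test(a, b) -> tuple[float, float]:
    """Two-sided paired t-test (df = n - 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need two equal-length samples with n >= 2")
    if np.ptp(a - b) == 0:
        raise ValueError("paired t-test undefined for zero-variance differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def format_mean_sd(values, decimals: int = 3) -> str:
    """Render a sample as ``mean +/- SD`` (e.g. ``0.903 +/- 0.023``)."""
    v = np.asarray(values, dtype=float)
    return f"{v.mean():.{decimals}f} ± {v.std(ddof=1):.{decimals}f}"


def format_bland_altman(x, y, decimals: int = 3, unit: str = "ppm") -> str:
    """Render limits of agreement as ``mean +/- half-width unit``."""
    mean, lo, hi = bland_altman(x, y)
    return f"{mean:.{decimals}f} ± {(hi - lo) / 2:.{decimals}f} {unit}"


# ------------------------------------------------------------------- reports
@dataclass
class AgreementReport:
    """Per-case metrics plus cohort-level agreement summaries."""

    per_case: pd.DataFrame       # subject_id, class_id, dice, volumes, chis
    summary: dict

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.per_case.to_csv(out_dir / "per_case.csv", index=False,
                             float_format="%.6f")
        (out_dir / "summary.json").write_text(
            json.dumps(self.summary, indent=2, sort_keys=True) + "\n")
        return out_dir


def _cohort_stats(df: pd.DataFrame) -> dict:
    out: dict = {"per_class": {}, "pooled": {}}
    for cid, grp in df.groupby("class_id"):
        entry = {
            "n": int(len(grp)),
            "dice_mean": float(grp.dice.mean()),
            "dice_sd": float(grp.dice.std(ddof=1)) if len(grp) > 1 else 0.0,
            "manual_volume_mean": float(grp.manual_volume.mean()),
            "auto_volume_mean": float(grp.auto_volume.mean()),
            "manual_susceptibility_mean": float(grp.manual_susceptibility.mean()),
            "auto_susceptibility_mean": float(grp.auto_susceptibility.mean()),
        }
        if len(grp) >= 3 and np.ptp(grp.manual_volume) > 0 and np.ptp(grp.auto_volume) > 0:
            r, p = pearson_correlation(grp.manual_volume, grp.auto_volume)
            entry["volume_pearson_r"], entry["volume_pearson_p"] = r, p
            r, p = pearson_correlation(grp.manual_susceptibility,
                                       grp.auto_susceptibility)
            entry["susceptibility_pearson_r"], entry["susceptibility_pearson_p"] = r, p
        if len(grp) >= 2:
            mean, lo, hi = bland_altman(grp.manual_susceptibility,
                                        grp.auto_susceptibility)
            entry["susceptibility_ba_mean"] = mean
            entry["susceptibility_ba_loa"] = [lo, hi]
        out["per_class"][int(cid)] = entry
    # pooled over classes and subjects (all nucleus observations concatenated)
    if len(df) >= 3:
        for quantity in ("volume", "susceptibility"):
            x = df[f"manual_{quantity}"].to_numpy()
            y = df[f"auto_{quantity}"].to_numpy()
            if np.ptp(x) > 0 and np.ptp(y) > 0:
                r, p = pearson_correlation(x, y)
                out["pooled"][f"{quantity}_pearson_r"] = r
                out["pooled"][f"{quantity}_pearson_p"] = p
            mean, lo, hi = bland_altman(x, y)
            out["pooled"][f"{quantity}_ba_mean"] = mean
            out["pooled"][f"{quantity}_ba_loa"] = [lo, hi]
    return out


def evaluate_cohort(pred_dir: str | Path, truth_dir: str | Path,
                    volumes_dir: str | Path, class_ids=None) -> AgreementReport:
    """Compare predicted vs manual label volumes over a cohort.

    Directories hold ``<subject>_labels.nii.gz`` (pred/truth) and
    ``<subject>_qsm.nii.gz`` (volumes); subject sets must match exactly.
    """
    pred_dir, truth_dir, volumes_dir = map(Path, (pred_dir, truth_dir, volumes_dir))

    def subjects(d, suffix):
        return {p.name.replace(suffix, ""): p for p in sorted(d.glob(f"*{suffix}"))}

    preds = subjects(pred_dir, "_labels.nii.gz")
    truths = subjects(truth_dir, "_labels.nii.gz")
    vols = subjects(volumes_dir, "_qsm.nii.gz")
    missing = (set(truths) ^ set(preds)) | (set(truths) ^ set(vols))
    if missing:
        raise ValueError(f"subject mismatch across directories: {sorted(missing)}")

    rows = []
    for sid in sorted(truths):
        vol = read_volume(vols[sid])
        truth = read_labels(truths[sid], vol)
        pred = read_labels(preds[sid], vol)
        ids = class_ids or sorted(truth.class_ids)
        for cid in ids:
            m = truth.data == cid
            a = pred.data == cid
            rows.append({
                "subject_id": sid,
                "class_id": cid,
                "dice": dice_coefficient(m, a),
                "manual_volume": region_volume(m, vol.voxel_size),
                "auto_volume": region_volume(a, vol.voxel_size),
                "manual_susceptibility": mean_susceptibility(vol.data, m)
                if m.any() else np.nan,
                "auto_susceptibility": mean_susceptibility(vol.data, a)
                if a.any() else np.nan,
            })
    df = pd.DataFrame(rows)
    return AgreementReport(per_case=df, summary=_cohort_stats(df))
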