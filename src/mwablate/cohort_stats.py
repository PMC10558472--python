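"""Cohort-level statistics and reporting.

Implements the statistical layer of the retrospective validation:
relative distance from the identity line (y-x)/x on model-vs-
manufacturer scatter data, a two-group Tukey 95% confidence-interval
range test between high-vascular-fraction cases and the rest of the
cohort, exclusion of artifact-flagged cases, box-and-whisker summaries
of the performance indicators, and scatter reports with the underlying
data exported alongside each figure.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError

__all__ = [
    "CaseRecord",
    "CohortTable",
    "TukeyResult",
    "identity_line_distance",
    "tukey_two_group",
    "apply_exclusions",
    "summarize",
    "scatter_report",
    "pearson_r",
]


@dataclass(frozen=True)
class CaseRecord:
    """One row of the cohort table: paired model/manufacturer indicators."""

    case_id: str
    predicted_volume_model_ml: float
    predicted_volume_manufacturer_ml: float
    gt_volume_ml: float
    dice_model: float
    dice_manufacturer: float
    aae_model_mm: float
    aae_manufacturer_mm: float
    vascular_fraction: float
    gt_overestimated: bool = False
    misaligned: bool = False

    def __post_init__(self) -> None:
        for name in ("predicted_volume_model_ml", "predicted_volume_manufacturer_ml",
                     "gt_volume_ml"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("dice_model", "dice_manufacturer"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class CohortTable:
    records: list[CaseRecord]
    provenance: dict = field(default_factory=dict)  # seeds, config hash

    def __post_init__(self) -> None:
        ids = [r.case_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("case ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: dict | None = None) -> "CohortTable":
        records = [CaseRecord(**{k: row[k] for k in CaseRecord.__dataclass_fields__})
                   for _, row in frame.iterrows()]
        return cls(records, provenance or {})


# ------------------------------------------------------------------ operations
def identity_line_distance(y: float, x: float) -> float:
    """Relative distance from the identity line, (y - x) / x."""
    if x == 0:
        raise UndefinedMetricError("identity-line distance undefined for x = 0")
    return (y - x) / x


@dataclass(frozen=True)
class TukeyResult:
    mean_difference: float     # mean(group True) - mean(group False)
    ci_low: float
    ci_high: float
    significant: bool
    alpha: float
    n_true: int
    n_false: int


def tukey_two_group(values, group, alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD 95% CI on the two-group mean difference of a statistic.

    For two groups this is the pooled-variance t interval scaled by the
    studentized-range quantile q(1-alpha; 2, N-2)/sqrt(2).  Significant
    iff the CI excludes zero.
    """
    from scipy.stats import studentized_range

    v = np.asarray(values, dtype=float)
    g = np.asarray(group, dtype=bool)
    if v.shape != g.shape:
        raise ValueError("values and group labels must align")
    a = v[g]
    b = v[~g]
    if len(a) < 2 or len(b) < 2:
        raise UndefinedMetricError("each group needs at least 2 cases")
    n = len(v)
    mean_diff = float(a.mean() - b.mean())
    ss = float(((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
    df = n - 2
    mse = ss / df
    q_crit = studentized_range.ppf(1.0 - alpha, 2, df)
    # Tukey-Kramer half width for unbalanced groups: q * sqrt(mse/2*(1/na+1/nb))
    half_width = q_crit * np.sqrt(mse / 2.0 * (1.0 / len(a) + 1.0 / len(b)))
    lo = mean_diff - half_width
    hi = mean_diff + half_width
    return TukeyResult(
        mean_difference=mean_diff,
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(lo > 0 or hi < 0),
        alpha=alpha,
        n_true=len(a),
        n_false=len(b),
    )


def apply_exclusions(table: CohortTable, criteria=("gt_overestimated", "misaligned"),
                     ) -> tuple[CohortTable, int]:
    """Drop rows carrying any of the selected artifact flags.

    Returns the filtered table and the number of removed rows.
    """
    valid = {"gt_overestimated", "misaligned"}
    bad = set(criteria) - valid
    if bad:
        raise ValueError(f"unknown exclusion criteria {sorted(bad)}")
    kept = [r for r in table.records
            if not any(getattr(r, c) for c in criteria)]
    removed = len(table.records) - len(kept)
    out = CohortTable(kept, {**table.provenance,
                             "excluded": removed,
                             "exclusion_criteria": sorted(criteria)})
    return out, removed


def _five_number(values: np.ndarray) -> dict:
    """Median/quartiles plus box-plot whiskers (1.5 IQR convention)."""
    v = np.sort(np.asarray(values, dtype=float))
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    whisker_lo = float(v[v >= lo_fence][0]) if np.any(v >= lo_fence) else float(v[0])
    whisker_hi = float(v[v <= hi_fence][-1]) if np.any(v <= hi_fence) else float(v[-1])
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "whisker_low": whisker_lo, "whisker_high": whisker_hi}


_INDICATORS = {
    "rel_vol_diff": ("predicted_volume_model_ml", "predicted_volume_manufacturer_ml"),
    "aae_mm": ("aae_model_mm", "aae_manufacturer_mm"),
    "dice": ("dice_model", "dice_manufacturer"),
}


def summarize(table: CohortTable) -> dict:
    """Five-number summaries per method plus paired model-manufacturer
    mean differences for |dV|/V_gt, AAE and Dice."""
    if len(table) == 0:
        raise UndefinedMetricError("cannot summarize an empty cohort table")
    frame = table.to_frame()
    gt = frame["gt_volume_ml"].to_numpy()
    derived = {
        "rel_vol_diff": {
            "model": np.abs(frame["predicted_volume_model_ml"].to_numpy() - gt) / gt,
            "manufacturer": np.abs(
                frame["predicted_volume_manufacturer_ml"].to_numpy() - gt) / gt,
        },
        "aae_mm": {
            "model": frame["aae_model_mm"].to_numpy(dtype=float),
            "manufacturer": frame["aae_manufacturer_mm"].to_numpy(dtype=float),
        },
        "dice": {
            "model": frame["dice_model"].to_numpy(dtype=float),
            "manufacturer": frame["dice_manufacturer"].to_numpy(dtype=float),
        },
    }
    out: dict = {"n_cases": len(table)}
    for indicator, per_method in derived.items():
        out[indicator] = {
            method: _five_number(vals) for method, vals in per_method.items()
        }
        paired = per_method["model"] - per_method["manufacturer"]
        out[indicator]["paired_mean_difference_model_minus_manufacturer"] = float(
            paired.mean())
    return out


def pearson_r(x, y) -> float:
    from scipy.stats import pearsonr

    return float(pearsonr(np.asarray(x, float), np.asarray(y, float)).statistic)


def scatter_report(table: CohortTable, mode: str, out_dir, vf_threshold: float = 0.05,
                   fmt: str = "svg") -> dict:
    """Emit a scatter figure and a flat CSV of the plotted points.

    Modes: ``volume`` (model vs manufacturer predicted volume with identity
    line), ``rel_diff`` (relative volume difference vs ground truth, model
    against manufacturer), ``dice_vs_vf`` (Dice difference against vascular
    fraction with zero line).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    if len(table) == 0:
        raise UndefinedMetricError("cannot plot an empty cohort table")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = table.to_frame()
    gt = frame["gt_volume_ml"].to_numpy()
    high_vf = frame["vascular_fraction"].to_numpy() > vf_threshold

    if mode == "volume":
        x = frame["predicted_volume_manufacturer_ml"].to_numpy()
        y = frame["predicted_volume_model_ml"].to_numpy()
        labels = ("manufacturer volume (mL)", "model volume (mL)")
        draw_identity = True
    elif mode == "rel_diff":
        x = np.abs(frame["predicted_volume_manufacturer_ml"].to_numpy() - gt) / gt
        y = np.abs(frame["predicted_volume_model_ml"].to_numpy() - gt) / gt
        labels = ("manufacturer |dV|/V_gt", "model |dV|/V_gt")
        draw_identity = True
    elif mode == "dice_vs_vf":
        x = frame["vascular_fraction"].to_numpy()
        y = frame["dice_model"].to_numpy() - frame["dice_manufacturer"].to_numpy()
        labels = ("vascular fraction", "Dice(model) - Dice(manufacturer)")
        draw_identity = False
    else:
        raise ValueError(f"unknown scatter mode {mode!r}")

    data = pd.DataFrame({"case_id": frame["case_id"], "x": x, "y": y,
                         "high_vascular_fraction": high_vf})
    csv_path = out_dir / f"scatter_{mode}.csv"
    data.to_csv(csv_path, index=False)

    fig, ax = plt.subplots(figsize=(5, 4.5))
    for flag, color, label in ((False, "tab:blue", f"VF <= {vf_threshold:.0%}"),
                               (True, "tab:red", f"VF > {vf_threshold:.0%}")):
        sel = high_vf == flag
        if sel.any():
            ax.scatter(x[sel], y[sel], c=color, label=label, s=28)
    if draw_identity:
        lim = [0.0, float(max(x.max(), y.max()) * 1.05)]
        ax.plot(lim, lim, "k--", lw=1, label="identity")
        ax.set_xlim(lim)
        ax.set_ylim(lim)
    else:
        ax.axhline(0.0, color="k", ls="--", lw=1)
    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[1])
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig_path = out_dir / f"scatter_{mode}.{fmt}"
    fig.savefig(fig_path)
    plt.close(fig)
    return {"figure": str(fig_path), "data": str(csv_path), "n_points": len(data)}
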