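"""Segmentation overlap metrics and stratified reporting.

Dice = 2|P∩T| / (|P|+|T|) measures overall overlap; TPF = |P∩T|/|T| is
pixel-level sensitivity; FPF = |P\\T| / |grid\\T| is the fraction of true
background claimed as lesion (1 - specificity).  The whole-background FPF
denominator is the convention under which published per-image FPF values of
~0.01 on images whose lesion covers a few percent of the frame are plausible;
FP/|T| is available via ``fpf_denominator="truth"`` for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import SegmentationMask

__all__ = [
    "EvaluationRecord",
    "dice",
    "tpf",
    "fpf",
    "evaluate_set",
    "paired_comparison",
]

log = logging.getLogger(__name__)


def _binary(mask, name: str) -> np.ndarray:
    m = mask.pixels if isinstance(mask, SegmentationMask) else np.asarray(mask)
    if not np.all(np.isin(m, (0, 1))):
        raise ValueError(f"{name} is not binary")
    return m.astype(bool)


def _pair(prediction, truth) -> tuple[np.ndarray, np.ndarray]:
    p = _binary(prediction, "prediction")
    t = _binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs truth {t.shape}")
    return p, t


def dice(prediction, truth) -> float:
    """Dice similarity 2|P∩T|/(|P|+|T|); 1.0 when both masks are empty."""
    p, t = _pair(prediction, truth)
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        log.warning("both masks empty: Dice defined as 1.0")
        return 1.0
    return 2.0 * int((p & t).sum()) / denom


def tpf(prediction, truth) -> float:
    """True positive fraction |P∩T|/|T| (pixel sensitivity)."""
    p, t = _pair(prediction, truth)
    nt = int(t.sum())
    if nt == 0:
        raise ValueError("TPF undefined for an empty truth mask")
    return int((p & t).sum()) / nt


def fpf(prediction, truth, denominator: str = "background") -> float:
    """False positive fraction: |P\\T| over true-background pixels.

    ``denominator="truth"`` switches to FP/|T| instead.
    """
    p, t = _pair(prediction, truth)
    fp = int((p & ~t).sum())
    if denominator == "background":
        nb = int((~t).sum())
        if nb == 0:
            raise ValueError("FPF undefined when truth covers the whole grid")
        return fp / nb
    elif denominator == "truth":
        nt = int(t.sum())
        if nt == 0:
            raise ValueError("FPF (truth denominator) undefined for empty truth")
        return fp / nt
    raise ValueError("denominator must be 'background' or 'truth'")


@dataclass
class EvaluationRecord:
    """Per-image Dice/TPF/FPF with stratum labels for grouped summaries."""

    image_id: str
    dice: float
    tpf: float
    fpf: float
    strata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in (("dice", self.dice), ("tpf", self.tpf), ("fpf", self.fpf)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def evaluate_pair(prediction, truth, image_id: str = "", strata: dict | None = None,
                  fpf_denominator: str = "background") -> EvaluationRecord:
    """All three metrics for one prediction/truth pair."""
    return EvaluationRecord(
        image_id=image_id,
        dice=dice(prediction, truth),
        tpf=tpf(prediction, truth),
        fpf=fpf(prediction, truth, denominator=fpf_denominator),
        strata=dict(strata or {}),
    )


def evaluate_set(records: list[EvaluationRecord], by: str | None = None) -> pd.DataFrame:
    """Mean ± std (plus boxplot quantiles) per stratum per metric.

    ``by`` names a stratum key; ``None`` gives a single "all" row.  Strata
    with zero members simply do not appear; a record missing the key is
    grouped under "unknown" with a warning.
    """
    if not records:
        raise ValueError("no evaluation records")
    rows = []
    for r in records:
        stratum = "all"
        if by is not None:
            if by not in r.strata:
                log.warning("record %s missing stratum %r", r.image_id, by)
                stratum = "unknown"
            else:
                stratum = str(r.strata[by])
        rows.append(
            {"stratum": stratum, "dice": r.dice, "tpf": r.tpf, "fpf": r.fpf,
             "image_id": r.image_id}
        )
    df = pd.DataFrame(rows)
    agg = df.groupby("stratum")[["dice", "tpf", "fpf"]].agg(
        ["mean", "std", "count", "min",
         ("q1", lambda s: s.quantile(0.25)),
         ("median", "median"),
         ("q3", lambda s: s.quantile(0.75)),
         "max"]
    )
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.fillna({c: 0.0 for c in agg.columns if c.endswith("_std")})


def boxplot_by_stratum(records: list[EvaluationRecord], by: str, path=None):
    """Boxplots of the three metrics per stratum (the paper-style figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strata = sorted({str(r.strata.get(by, "unknown")) for r in records})
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.4))
    for ax, metric in zip(axes, ("dice", "tpf", "fpf")):
        data = [
            [getattr(r, metric) for r in records if str(r.strata.get(by, "unknown")) == s]
            for s in strata
        ]
        ax.boxplot(data, tick_labels=strata)
        ax.set_title(metric.upper() if metric != "dice" else "Dice")
        ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def paired_comparison(
    records_a: list[EvaluationRecord],
    records_b: list[EvaluationRecord],
    metric: str = "dice",
    test: str = "wilcoxon",
) -> dict:
    """Two-tailed paired test on per-image metric values of two methods.

    Records are paired by ``image_id``; mismatched sets are an error.  The
    default is the Wilcoxon signed-rank test (no normality assumption on
    per-image Dice differences); ``test="ttest"`` gives the paired t-test.
    Identical inputs (all-zero differences) return p = 1.0 by convention.
    """
    a = {r.image_id: getattr(r, metric) for r in records_a}
    b = {r.image_id: getattr(r, metric) for r in records_b}
    if set(a) != set(b):
        missing = set(a) ^ set(b)
        raise ValueError(f"records are not paired; unmatched ids: {sorted(missing)[:5]}")
    ids = sorted(a)
    xa = np.array([a[i] for i in ids])
    xb = np.array([b[i] for i in ids])
    diffs = xa - xb
    if test == "wilcoxon":
        if np.all(diffs == 0):
            return {"statistic": 0.0, "p_value": 1.0, "n": len(ids), "test": test}
        stat, p = stats.wilcoxon(xa, xb, alternative="two-sided")
    elif test == "ttest":
        if np.all(diffs == diffs[0]):
            # zero-variance differences: degenerate for the t-test
            p = 1.0 if diffs[0] == 0 else 0.0
            stat = np.inf if diffs[0] != 0 else 0.0
        else:
            stat, p = stats.ttest_rel(xa, xb)
    else:
        raise ValueError("test must be 'wilcoxon' or 'ttest'")
    return {"statistic": float(stat), "p_value": float(p), "n": len(ids), "test": test}
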