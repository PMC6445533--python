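"""Read-count-ratio evaluation: fidelity, ROC/auROC, specificity ratio.

Fidelity asks whether intensity ordering reflects affinity ordering: over
sampled pairs of loci whose read-count ratios differ by at least a margin
(default 10%), it is the fraction where the higher-ratio locus has the
strictly lower binding energy.  The ROC machinery scores how well the
ratio separates loci that carry a target-TF site from those that do not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc, roc_curve

__all__ = ["FidelityQuery", "ROCResult", "fidelity", "roc_auc", "specificity_ratio"]

_BINS = ("all", "top25", "25-50", "50-75", "bottom25")


@dataclass(frozen=True)
class FidelityQuery:
    """Pair-sampling settings for the fidelity statistic."""

    n_pairs: int = 1000
    margin: float = 0.10
    bin: str = "all"

    def __post_init__(self):
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if self.bin not in _BINS:
            raise ValueError(f"bin must be one of {_BINS}")


def _bin_indices(ratios: np.ndarray, which: str) -> np.ndarray:
    """Indices of defined ratios falling in the requested percentile bin.

    Percentiles are computed on defined ratios only; ties break by stable
    sort on locus id, so the bins partition the loci exactly.
    """
    defined = np.flatnonzero(np.isfinite(ratios))
    if which == "all":
        return defined
    order = defined[np.argsort(ratios[defined], kind="stable")]  # ascending
    m = order.size
    edges = [0, m // 4, m // 2, 3 * m // 4, m]
    parts = {
        "bottom25": order[edges[0] : edges[1]],
        "25-50": order[edges[1] : edges[2]],
        "50-75": order[edges[2] : edges[3]],
        "top25": order[edges[3] : edges[4]],
    }
    return parts[which]


def fidelity(ratios, energies, query: FidelityQuery = FidelityQuery(), rng=0) -> float:
    """Probability that a >= (1+margin)-fold higher ratio implies lower energy.

    Pairs are sampled uniformly within the chosen percentile bin; pairs not
    meeting the margin are excluded (conditional reading).  Energy ties
    count as failures.  Returns NaN when no sampled pair qualifies.
    """
    ratios = np.asarray(ratios, dtype=float)
    energies = np.asarray(energies, dtype=float)
    if ratios.shape != energies.shape:
        raise ValueError("ratios and energies must align")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pool = _bin_indices(ratios, query.bin)
    if pool.size < 2:
        raise ValueError(f"bin {query.bin!r} holds fewer than 2 loci")
    i = pool[rng.integers(0, pool.size, size=query.n_pairs)]
    j = pool[rng.integers(0, pool.size, size=query.n_pairs)]
    keep = i != j
    i, j = i[keep], j[keep]
    # orient each pair so i is the higher-ratio locus
    swap = ratios[i] < ratios[j]
    i[swap], j[swap] = j[swap], i[swap].copy()
    qualifies = ratios[i] >= (1.0 + query.margin) * ratios[j]
    if not np.any(qualifies):
        return float("nan")
    correct = energies[i][qualifies] < energies[j][qualifies]
    return float(correct.mean())


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auroc: float

    def tpr_at_fpr(self, fpr_target: float) -> float:
        """TPR at a given FPR, linearly interpolated along the curve."""
        return float(np.interp(fpr_target, self.fpr, self.tpr))


def roc_auc(ratios, labels) -> ROCResult:
    """ROC curve and auROC of read-count ratios against binary site labels.

    Equivalent to the normalised Mann-Whitney U statistic of the two
    ratio samples.  Loci with undefined ratios are dropped.
    """
    ratios = np.asarray(ratios, dtype=float)
    labels = np.asarray(labels).astype(int)
    keep = np.isfinite(ratios)
    ratios, labels = ratios[keep], labels[keep]
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(labels, ratios)
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auroc=float(auc(fpr, tpr)))


def specificity_ratio(occ_tp, occ_fp, ext_tp=None, ext_fp=None) -> float:
    """Antibody-specificity ratio r_e: mean fragment yield TP over FP loci.

    r_e = mean(p_b * p_e | TP) / mean(p_b * p_e | FP).  With equal
    extraction efficiencies this reduces to the mean occupancy ratio; with
    equal occupancies, to the mean extraction-efficiency ratio.
    """
    occ_tp = np.asarray(occ_tp, dtype=float)
    occ_fp = np.asarray(occ_fp, dtype=float)
    if occ_tp.size == 0 or occ_fp.size == 0:
        raise ValueError("both groups must be nonempty")
    wt = occ_tp * (1.0 if ext_tp is None else np.asarray(ext_tp, dtype=float))
    wf = occ_fp * (1.0 if ext_fp is None else np.asarray(ext_fp, dtype=float))
    denom = np.mean(wf)
    if denom == 0:
        raise ValueError("zero denominator: false-positive yield is zero")
    return float(np.mean(wt) / denom)
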