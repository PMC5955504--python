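"""Ten-fold patient-grouped training and majority-vote fusion.

The ensemble idea: train ten U-nets, each validated on a different tenth of
the patients (9:1 split, grouped so a patient never straddles train and
validation), then fuse their binarized per-pixel predictions by equally
weighted averaging and a vote threshold.  Random initialization sends each
member to a different local minimum; voting removes the idiosyncratic
outlier regions of individual members and tightens the low-confidence
periphery of the predicted mass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator

from .network import NetworkConfig, UNet, ProbabilityMap, train_member
from .phantom import SegmentationMask

__all__ = [
    "FoldPlan",
    "EnsembleConfig",
    "make_folds",
    "train_ensemble",
    "majority_vote",
    "vote_threshold_sweep",
    "member_count_sweep",
    "MultiUNetEnsemble",
]


@dataclass(frozen=True)
class FoldPlan:
    """Patient -> fold assignment; every patient in exactly one fold."""

    n_folds: int
    assignments: dict
    rng_seed: int = 0

    def fold_of(self, patient_id) -> int:
        return self.assignments[patient_id]

    def patients_in(self, fold: int) -> list:
        return sorted(p for p, f in self.assignments.items() if f == fold)


@dataclass(frozen=True)
class EnsembleConfig:
    """Fusion parameters: binarize members at 0.5, vote threshold 0.5."""

    vote_threshold: float = 0.5
    member_binarize_threshold: float = 0.5
    n_members: int = 10
    average_probabilities: bool = False  # paper method averages *binary* pixels

    def __post_init__(self) -> None:
        for name, v in (("vote_threshold", self.vote_threshold),
                        ("member_binarize_threshold", self.member_binarize_threshold)):
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")


def make_folds(patient_ids, n_folds: int = 10, rng_seed: int = 0) -> FoldPlan:
    """Shuffle patients and deal them into ``n_folds`` near-equal folds.

    Fold sizes differ by at most one patient; which folds get the remainder
    is decided by the seeded shuffle.  All images of a patient share its fold.
    """
    patients = sorted(set(patient_ids))
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    if n_folds > len(patients):
        raise ValueError(
            f"more folds ({n_folds}) than patients ({len(patients)})"
        )
    rng = np.random.default_rng(rng_seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    assignments = {}
    for k, chunk in enumerate(np.array_split(np.arange(len(order)), n_folds)):
        for i in chunk:
            assignments[order[i]] = k
    return FoldPlan(n_folds=n_folds, assignments=assignments, rng_seed=rng_seed)


def train_ensemble(
    dataset: list[tuple[np.ndarray, np.ndarray, str]],
    fold_plan: FoldPlan,
    net_config: NetworkConfig,
    rng_seed: int = 0,
    augment_config=None,
) -> list[dict]:
    """Train one member per fold: member k validates on fold k, trains on the rest.

    ``dataset`` is a list of (standardized image, binary mask, patient_id)
    triples on the network input grid.  Members get independent random
    initializations derived from ``rng_seed``.  Returns a list of dicts
    ``{"model": UNet, "fold": k, "history": ..., "val_dice": ...}``.
    """
    pats = {t[2] for t in dataset}
    missing = pats - set(fold_plan.assignments)
    if missing:
        raise ValueError(f"fold plan does not cover patients: {sorted(missing)[:5]}")
    seeds = np.random.SeedSequence(rng_seed).spawn(fold_plan.n_folds)
    members = []
    for k in range(fold_plan.n_folds):
        train = [t for t in dataset if fold_plan.fold_of(t[2]) != k]
        val = [t for t in dataset if fold_plan.fold_of(t[2]) == k]
        if not train or not val:
            raise ValueError(f"fold {k}: empty training or validation partition")
        member_rng = np.random.default_rng(seeds[k])
        member_seed = int(member_rng.integers(0, 2**31 - 1))
        model = UNet(replace(net_config, rng_seed=member_seed),
                     rng=np.random.default_rng(member_seed))
        history = train_member(model, train, val, model.config,
                               rng_seed=member_seed, augment_config=augment_config)
        members.append(
            {"model": model, "fold": k, "history": history,
             "val_dice": history["best_val_dice"]}
        )
    return members


def _stack_maps(maps) -> np.ndarray:
    arrs = [np.asarray(getattr(m, "pixels", m), dtype=np.float64) for m in maps]
    if not arrs:
        raise ValueError("no probability maps to fuse")
    shape = arrs[0].shape
    for a in arrs:
        if a.shape != shape:
            raise ValueError(f"mixed grids in vote: {a.shape} vs {shape}")
    return np.stack(arrs)


def majority_vote(maps, config: EnsembleConfig | None = None) -> SegmentationMask:
    """Fuse member probability maps into one binary mask by majority voting.

    Each map is binarized at ``member_binarize_threshold``; the equally
    weighted binary maps are averaged; a pixel is lesion iff the average
    meets ``vote_threshold``.  The tie (average exactly equal to the
    threshold, e.g. 5 votes of 10 at 0.5) counts as positive — the inclusive
    convention, fixed here so it is testable.
    """
    config = config or EnsembleConfig()
    stack = _stack_maps(maps)
    if config.average_probabilities:
        avg = stack.mean(axis=0)
    else:
        votes = stack >= config.member_binarize_threshold
        avg = votes.mean(axis=0)
    return SegmentationMask((avg >= config.vote_threshold).astype(np.uint8),
                            role="prediction")


def vote_threshold_sweep(
    maps_per_image: list[list],
    truths: list,
    thresholds,
    config: EnsembleConfig | None = None,
) -> dict[float, float]:
    """Mean Dice over the evaluation set at each vote threshold.

    Raising the threshold can only shrink the predicted-positive set of each
    image (vote fractions are fixed; the threshold test is monotone).
    """
    from .metrics import dice as _dice

    thresholds = list(thresholds)
    if len(thresholds) < 2:
        raise ValueError("need at least 2 thresholds to sweep")
    if not maps_per_image:
        raise ValueError("empty evaluation set")
    base = config or EnsembleConfig()
    curve = {}
    for t in thresholds:
        cfg = replace(base, vote_threshold=t)
        scores = [
            _dice(majority_vote(maps, cfg).pixels, np.asarray(
                getattr(truth, "pixels", truth)))
            for maps, truth in zip(maps_per_image, truths)
        ]
        curve[float(t)] = float(np.mean(scores))
    return curve


def member_count_sweep(
    maps_per_image: list[list],
    truths: list,
    counts,
    config: EnsembleConfig | None = None,
    n_subsets: int = 1,
    rng_seed: int = 0,
) -> dict[int, float]:
    """Mean Dice of the fused mask as a function of ensemble size.

    For each count m the first m members (fold order) are fused; with
    ``n_subsets`` > 1 the result is additionally averaged over seeded random
    m-member subsets, mirroring a variance-over-evaluations error bar.
    """
    from .metrics import dice as _dice

    cfg = config or EnsembleConfig()
    n_members = len(maps_per_image[0]) if maps_per_image else 0
    if not maps_per_image:
        raise ValueError("empty evaluation set")
    rng = np.random.default_rng(rng_seed)
    curve = {}
    for m in counts:
        m = int(m)
        if m < 1 or m > n_members:
            raise ValueError(f"member count {m} outside [1, {n_members}]")
        subsets = [list(range(m))]
        for _ in range(n_subsets - 1):
            subsets.append(sorted(rng.choice(n_members, size=m, replace=False)))
        scores = []
        for subset in subsets:
            for maps, truth in zip(maps_per_image, truths):
                fused = majority_vote([maps[i] for i in subset], cfg)
                scores.append(_dice(fused.pixels,
                                    np.asarray(getattr(truth, "pixels", truth))))
        curve[m] = float(np.mean(scores))
    return curve


class MultiUNetEnsemble(BaseEstimator):
    """The voting ensemble as a scikit-learn-style estimator.

    ``fit(X, y, groups)`` runs grouped k-fold member training; ``predict``
    fuses member predictions by majority voting; ``predict_proba`` returns the
    per-pixel vote fraction (the fraction of members that call the pixel
    lesion).  ``X``: (n, H, W) standardized images on the member input grid;
    ``y``: aligned binary masks; ``groups``: patient identifiers.
    """

    def __init__(
        self,
        net_config: NetworkConfig | None = None,
        n_folds: int = 10,
        vote_threshold: float = 0.5,
        member_binarize_threshold: float = 0.5,
        augment: bool = True,
        random_state: int = 0,
    ):
        self.net_config = net_config
        self.n_folds = n_folds
        self.vote_threshold = vote_threshold
        self.member_binarize_threshold = member_binarize_threshold
        self.augment = augment
        self.random_state = random_state

    def _ensemble_config(self) -> EnsembleConfig:
        return EnsembleConfig(
            vote_threshold=self.vote_threshold,
            member_binarize_threshold=self.member_binarize_threshold,
            n_members=self.n_folds,
        )

    def fit(self, X, y, groups=None):
        from .preprocess import PreprocessConfig

        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if groups is None:
            groups = [f"im{i}" for i in range(len(X))]
        cfg = self.net_config or NetworkConfig()
        self.fold_plan_ = make_folds(groups, self.n_folds, rng_seed=self.random_state)
        dataset = list(zip(X, y, groups))
        aug = PreprocessConfig() if self.augment else None
        self.members_ = train_ensemble(
            dataset, self.fold_plan_, cfg, rng_seed=self.random_state,
            augment_config=aug,
        )
        self.member_val_dice_ = [m["val_dice"] for m in self.members_]
        return self

    def member_maps(self, X) -> list[list[ProbabilityMap]]:
        """Per-image list of per-member probability maps (fold order)."""
        X = np.asarray(X, dtype=np.float32)
        per_member = []
        for m in self.members_:
            probs = []
            for i in range(0, len(X), 8):
                probs.append(m["model"].predict_proba(X[i : i + 8]))
            per_member.append(np.concatenate(probs, axis=0))
        return [
            [ProbabilityMap(per_member[k][i], model_id=f"fold{k}")
             for k in range(len(self.members_))]
            for i in range(len(X))
        ]

    def predict_proba(self, X) -> np.ndarray:
        """Vote fraction per pixel, shape (n, h, w)."""
        cfg = self._ensemble_config()
        out = []
        for maps in self.member_maps(X):
            stack = _stack_maps(maps)
            out.append((stack >= cfg.member_binarize_threshold).mean(axis=0))
        return np.stack(out)

    def predict(self, X) -> np.ndarray:
        cfg = self._ensemble_config()
        return np.stack(
            [majority_vote(maps, cfg).pixels for maps in self.member_maps(X)]
        )

    def score(self, X, y) -> float:
        from .metrics import dice as _dice

        preds = self.predict(X)
        return float(np.mean([_dice(p, t) for p, t in zip(preds, np.asarray(y))]))
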