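"""Genuine/impostor trial construction, FAR/FRR, DET curve, EER threshold
calibration, and the four-case (seen/unseen x genuine/impostor) accuracy
matrix for open-set evaluation.

A trial compares an enrollment fingerprint (built from a subject's first
session) with a probe fingerprint (built from a disjoint segment of a later
session).  FAR counts impostor trials at or under the threshold; FRR counts
genuine trials over it.  The operating threshold is calibrated at the
equal-error-rate point of the DET curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .authentication import AuthPolicy, distance
from .errors import ShapeError, UndefinedRateError
from .fingerprint_model import FingerprintFunction, fingerprint_sample
from .preprocess import WindowParams
from .signal_io import EegRecording
from .synthetic_data import sessions_of

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSplit",
    "Trial",
    "TrialSet",
    "compute_fingerprint_table",
    "build_trials",
    "far_frr",
    "det_curve",
    "DetCurve",
    "eer_threshold",
    "EerPoint",
    "four_case_matrix",
    "accuracy_precision_recall",
]


@dataclass(frozen=True)
class CohortSplit:
    """Alpha (training cohort) vs Beta (never-seen) subject split."""

    alpha_ids: tuple[str, ...]
    beta_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.alpha_ids) & set(self.beta_ids):
            raise ShapeError("alpha and beta subject sets must be disjoint")

    def group_of(self, subject_id: str) -> str:
        if subject_id in self.alpha_ids:
            return "alpha"
        if subject_id in self.beta_ids:
            return "beta"
        raise ShapeError(f"subject {subject_id!r} in neither split group")


@dataclass(frozen=True)
class Trial:
    claimed: str          # enrolled identity being claimed
    probe_subject: str    # true owner of the probe sample
    probe_index: int
    group: str            # split group of the claimed identity
    genuine: bool
    distance: float


@dataclass
class TrialSet:
    """All genuine and impostor verification trials under one metric."""

    distance_name: str
    trials: list[Trial]

    @property
    def genuine_distances(self) -> np.ndarray:
        return np.array([t.distance for t in self.trials if t.genuine])

    @property
    def impostor_distances(self) -> np.ndarray:
        return np.array([t.distance for t in self.trials if not t.genuine])

    def subset(self, predicate) -> "TrialSet":
        return TrialSet(self.distance_name,
                        [t for t in self.trials if predicate(t)])

    def __len__(self) -> int:
        return len(self.trials)


def compute_fingerprint_table(
    cohort: list[EegRecording],
    f: FingerprintFunction,
    channels,
    params: WindowParams,
    probes_per_subject: int = 2,
    orthogonalize_flag: bool = True,
) -> dict[str, dict]:
    """Enrollment and probe fingerprints per subject.

    Enrollment uses each subject's first session; probes are
    ``probes_per_subject`` disjoint contiguous segments of the second
    session (honest, leakage-free protocol).  Subjects with a single session
    are excluded with a warning.  Returns
    ``{subject_id: {"enroll": vec, "probes": [vec, ...]}}``.
    """
    table: dict[str, dict] = {}
    for sid in sorted({r.subject_id for r in cohort}):
        sessions = sessions_of(cohort, sid)
        if len(sessions) < 2:
            logger.warning(
                "subject %s has a single session; excluded from trials", sid
            )
            continue
        enroll_rec, probe_rec = sessions[0], sessions[1]
        gamma = params.gamma
        seg_len = probe_rec.n_samples // probes_per_subject
        if seg_len < gamma:
            logger.warning(
                "subject %s: probe session too short for %d disjoint "
                "segments; excluded", sid, probes_per_subject,
            )
            continue
        enroll_fp = fingerprint_sample(
            f, enroll_rec, channels, params, orthogonalize_flag=orthogonalize_flag
        )
        probes = []
        for p in range(probes_per_subject):
            segment = probe_rec.slice_samples(p * seg_len, (p + 1) * seg_len)
            probes.append(fingerprint_sample(
                f, segment, channels, params,
                orthogonalize_flag=orthogonalize_flag,
            ))
        table[sid] = {"enroll": enroll_fp, "probes": probes}
    return table


def build_trials(
    cohort: list[EegRecording],
    f: FingerprintFunction,
    channels,
    params: WindowParams,
    split: CohortSplit,
    pairing_seed: int = 0,
    distance_name: str = "cosine",
    probes_per_subject: int = 2,
    max_impostors_per_claim: int | None = None,
    table: dict | None = None,
    orthogonalize_flag: bool = True,
) -> TrialSet:
    """Construct all genuine and impostor trials.

    Genuine: each subject's enrollment fingerprint against each of its own
    probes (s x p trials for s subjects, p probes each).  Impostor: each
    enrollment fingerprint against every other subject's probes
    (s x (s-1) x p trials), optionally subsampled to
    ``max_impostors_per_claim`` impostor subjects drawn with
    ``pairing_seed``.  Trials are labelled by the claimed identity's split
    group.
    """
    if table is None:
        table = compute_fingerprint_table(
            cohort, f, channels, params,
            probes_per_subject=probes_per_subject,
            orthogonalize_flag=orthogonalize_flag,
        )
    rng = np.random.default_rng(pairing_seed)
    subjects = sorted(table)
    trials: list[Trial] = []
    for claimed in subjects:
        enroll_vec = table[claimed]["enroll"].values
        group = split.group_of(claimed)
        for j, probe in enumerate(table[claimed]["probes"]):
            trials.append(Trial(
                claimed=claimed, probe_subject=claimed, probe_index=j,
                group=group, genuine=True,
                distance=distance(enroll_vec, probe.values, distance_name),
            ))
        others = [s for s in subjects if s != claimed]
        if max_impostors_per_claim is not None and len(others) > max_impostors_per_claim:
            idx = rng.choice(len(others), max_impostors_per_claim, replace=False)
            others = [others[i] for i in sorted(idx)]
        for other in others:
            for j, probe in enumerate(table[other]["probes"]):
                trials.append(Trial(
                    claimed=claimed, probe_subject=other, probe_index=j,
                    group=group, genuine=False,
                    distance=distance(enroll_vec, probe.values, distance_name),
                ))
    return TrialSet(distance_name=distance_name, trials=trials)


def far_frr(trials: TrialSet, threshold: float) -> tuple[float, float]:
    """(FAR, FRR) at a threshold: FAR = impostors accepted (<=) / impostors;
    FRR = genuines rejected (>) / genuines."""
    gen = trials.genuine_distances
    imp = trials.impostor_distances
    if gen.size == 0 or imp.size == 0:
        raise UndefinedRateError(
            "FAR/FRR need both genuine and impostor trials "
            f"(have {gen.size} genuine, {imp.size} impostor)"
        )
    far = float((imp <= threshold).mean())
    frr = float((gen > threshold).mean())
    return far, frr


@dataclass
class DetCurve:
    """Ordered (threshold, FAR, FRR) triples over an increasing grid."""

    thresholds: np.ndarray
    far: np.ndarray
    frr: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        self.far = np.asarray(self.far, dtype=np.float64)
        self.frr = np.asarray(self.frr, dtype=np.float64)
        if not (len(self.thresholds) == len(self.far) == len(self.frr)):
            raise ShapeError("curve arrays must have equal length")

    def __len__(self) -> int:
        return len(self.thresholds)


def _default_grid(trials: TrialSet) -> np.ndarray:
    pooled = np.sort(np.concatenate([
        trials.genuine_distances, trials.impostor_distances
    ]))
    mids = (pooled[1:] + pooled[:-1]) / 2.0
    span = max(pooled[-1] - pooled[0], 1.0)
    below = pooled[0] - 1e-9 * span
    above = pooled[-1] + 1e-9 * span
    # include the exact pooled values too: acceptance is <=, so a threshold
    # equal to a distance is achievable and distinct from the midpoint below
    grid = np.unique(np.concatenate([[below], pooled, mids, [above]]))
    return grid


def det_curve(trials: TrialSet, threshold_grid=None) -> DetCurve:
    """FAR/FRR over a threshold grid.

    The default grid uses all pooled distances, the midpoints between
    consecutive distinct values, and one point below/above the extremes, so
    every achievable (FAR, FRR) pair appears on the curve.
    """
    if threshold_grid is None:
        grid = _default_grid(trials)
    else:
        grid = np.sort(np.asarray(threshold_grid, dtype=np.float64))
        if grid.size == 0:
            raise ShapeError("threshold grid must be non-empty")
    rates = [far_frr(trials, t) for t in grid]
    far = np.array([r[0] for r in rates])
    frr = np.array([r[1] for r in rates])
    return DetCurve(thresholds=grid, far=far, frr=frr)


@dataclass(frozen=True)
class EerPoint:
    threshold: float
    eer: float
    far_at_threshold: float
    frr_at_threshold: float


def eer_threshold(curve: DetCurve) -> EerPoint:
    """Operating point of the DET curve: the last point of its bottom-left
    corner.

    Among grid points minimizing |FAR - FRR|, those with the smallest total
    error FAR + FRR are kept, and of these the highest threshold wins — when
    the calibration distances separate cleanly, that is the most permissive
    zero-error threshold, sitting at the far edge of the genuine/impostor
    margin.  EER is the mean of FAR and FRR there.
    """
    if len(curve) == 0:
        raise ShapeError("empty DET curve")
    gap = np.abs(curve.far - curve.frr)
    m1 = np.flatnonzero(gap == gap.min())
    total = curve.far[m1] + curve.frr[m1]
    m2 = m1[total == total.min()]
    i = int(m2[-1])  # thresholds ascend: last index = highest threshold
    return EerPoint(
        threshold=float(curve.thresholds[i]),
        eer=float((curve.far[i] + curve.frr[i]) / 2.0),
        far_at_threshold=float(curve.far[i]),
        frr_at_threshold=float(curve.frr[i]),
    )


def four_case_matrix(trials: TrialSet, policy: AuthPolicy) -> dict[str, float | None]:
    """Per-cell accuracy over {alpha, beta} x {genuine, impostor}.

    A genuine trial is correct when accepted (distance <= threshold); an
    impostor trial when rejected.  Empty cells are reported as ``None``.
    """
    if policy.distance_name != trials.distance_name:
        raise ShapeError(
            f"policy distance {policy.distance_name!r} != trial distance "
            f"{trials.distance_name!r}"
        )
    out: dict[str, float | None] = {}
    for group in ("alpha", "beta"):
        for genuine in (True, False):
            cell = [t for t in trials.trials
                    if t.group == group and t.genuine == genuine]
            key = f"{group}_{'genuine' if genuine else 'impostor'}"
            if not cell:
                out[key] = None
                continue
            correct = sum(
                (t.distance <= policy.threshold) == t.genuine for t in cell
            )
            out[key] = correct / len(cell)
    return out


def accuracy_precision_recall(
    trials: TrialSet, policy: AuthPolicy
) -> tuple[float, float | None, float | None]:
    """Overall accuracy, precision, recall with genuine-accept as positive.

    Undefined ratios (zero denominators) are returned as ``None``.
    """
    if policy.distance_name != trials.distance_name:
        raise ShapeError("policy/trial distance mismatch")
    if not trials.trials:
        raise UndefinedRateError("empty trial set")
    tp = fp = tn = fn = 0
    for t in trials.trials:
        accepted = t.distance <= policy.threshold
        if t.genuine and accepted:
            tp += 1
        elif t.genuine:
            fn += 1
        elif accepted:
            fp += 1
        else:
            tn += 1
    accuracy = (tp + tn) / len(trials.trials)
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    return accuracy, precision, recall
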