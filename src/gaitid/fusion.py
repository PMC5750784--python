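"""Multi-sensor fusion of the per-source identifiers.

Two complementary strategies are provided:

* **Early fusion** stacks the ten per-source TF images of one gait cycle
  along the channel axis (5 sensors x 2 modalities x RGB = 30 channels) and
  feeds one wider classifier.

* **Late fusion** combines the per-source log-likelihood score vectors
  S_i(x) = {S_ij(x)} at the decision level.  The fused score for subject j is
  the subject-dependent weighted sum  Score_j(x) = sum_i w_ij * S_ij(x);
  scores are then normalized to log-likelihood ratios against the average
  evidence for the competing subjects,

      LLR_phi(x) = Score_phi(x) - log( (1/(M-1)) * sum_{j != phi} exp(Score_j(x)) ),

  and the segment is detected as subject phi when LLR_phi(x) > theta_phi.

**Minimum error score fusion (MESF)** learns the N x M non-negative weights
w_ij iteratively: starting from w == 1 (which makes the first iterate the
plain SUM fusion), each weight w_{i,phi} in turn is re-estimated by an exact
threshold scan.  For every training segment the weight value at which the
segment crosses the subject-phi decision boundary (all other weights fixed) is

      Theta_{i,phi}(x) = C(x) / S_{i,phi}(x),
      C(x) = theta_phi + log<(1/(M-1)) sum_{j != phi} exp(Score_j(x))>
             - sum_{k != i} w_{k,phi} S_{k,phi}(x),

derived directly from the LLR decision rule (note: with exp(+Score_j) in the
competitor average, the algebraically self-consistent form).  Candidate
weights -- zero, the current value, midpoints between successive ranked
Theta values, and one step past the largest -- are scored by the exact
identification error of the fusion on the training segments, and the best
candidate is kept; since the current value is always a candidate the
recorded error trace is non-increasing by construction, and the converged
MESF training error never exceeds the SUM-fusion training error it starts
from (unit weights are exactly the SUM fusion).

SUM fusion and a one-vs-rest linear SVM over the concatenated score vector
are included as reference combiners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.special import logsumexp
from sklearn.svm import SVC

from .preprocess import MODALITIES, SENSOR_LOCATIONS
from .tfr import TFImage

#: Fixed channel order of early fusion: sensor 1..5, within each acc then gyro.
CANONICAL_SOURCES: List[Tuple[int, str]] = [
    (s, m) for s in sorted(SENSOR_LOCATIONS) for m in MODALITIES
]


# ---------------------------------------------------------------------------
# Score containers
# ---------------------------------------------------------------------------

@dataclass
class ScoreTensor:
    """Per-segment scores of all models: (segments, models, subjects)."""

    scores: np.ndarray  # (T, N, M) log-likelihood scores S_{i,j}(x_t)
    labels: np.ndarray  # (T,) true subject ids in 1..M

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.ndim != 3:
            raise ValueError("scores must be (segments, models, subjects)")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        T, N, M = self.scores.shape
        if N < 1 or M < 2:
            raise ValueError("need N >= 1 models and M >= 2 subjects")
        if len(self.labels) != T:
            raise ValueError("one label per segment required")

    @property
    def n_models(self) -> int:
        return self.scores.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[2]


@dataclass
class FusionWeights:
    """Learned subject-dependent fusion weights and decision thresholds."""

    w: np.ndarray       # (N, M), all >= 0
    theta: np.ndarray   # (M,)
    error_trace: List[int] = field(default_factory=list)

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if np.any(self.w < 0):
            raise ValueError("fusion weights live in [0, inf)")


@dataclass
class SvmFusionModel:
    """One-vs-rest maximum-margin combiners over the concatenated score vector."""

    classifiers: List[SVC]
    n_models: int
    n_subjects: int


# ---------------------------------------------------------------------------
# Early fusion
# ---------------------------------------------------------------------------

def early_fuse(images: Union[Dict[Tuple[int, str], TFImage],
                             Sequence[TFImage]]) -> TFImage:
    """Stack the ten per-source images of one cycle into one 30-channel image.

    Accepts a dict keyed by (sensor_id, modality) or a sequence already in
    canonical order.  The channel order is fixed and documented:
    sensor 1..5 x (acc, gyro) x RGB.
    """
    if isinstance(images, dict):
        missing = [k for k in CANONICAL_SOURCES if k not in images]
        if missing:
            raise ValueError(f"early fusion is missing sources: {missing}")
        ordered = [images[k] for k in CANONICAL_SOURCES]
    else:
        ordered = list(images)
        if len(ordered) != len(CANONICAL_SOURCES):
            raise ValueError(f"early fusion needs exactly "
                             f"{len(CANONICAL_SOURCES)} images, got {len(ordered)}")
    shape = ordered[0].pixels.shape
    cycle_ids = set()
    for img in ordered:
        if img.pixels.shape != shape:
            raise ValueError("early fusion requires identically shaped images")
        if len(img.provenance) >= 3:
            cycle_ids.add(img.provenance[2])
    if len(cycle_ids) > 1:
        raise ValueError(f"images come from different cycles: {sorted(cycle_ids)}")
    pixels = np.concatenate([img.pixels for img in ordered], axis=2)
    return TFImage(pixels=pixels, label=ordered[0].label,
                   provenance=("early",) + tuple(sorted(cycle_ids)))


# ---------------------------------------------------------------------------
# Score arithmetic
# ---------------------------------------------------------------------------

def fuse_scores(S: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted fused score per subject: Score_j = sum_i w_ij * S_ij.

    ``S`` may be one (N, M) row or a (T, N, M) stack.
    """
    S = np.asarray(S, dtype=float)
    w = np.asarray(w, dtype=float)
    if S.shape[-2:] != w.shape:
        raise ValueError(f"shape mismatch: scores {S.shape} vs weights {w.shape}")
    return np.einsum("...nm,nm->...m", S, w)


def sum_fusion(S: np.ndarray) -> np.ndarray:
    """Unweighted score sum across models (fuse_scores with all-ones weights)."""
    S = np.asarray(S, dtype=float)
    return S.sum(axis=-2)


def llr_normalize(scores: np.ndarray) -> np.ndarray:
    """Log-likelihood-ratio normalization against the competitor average.

    LLR_phi = Score_phi - log((1/(M-1)) sum_{j != phi} exp(Score_j)), computed
    with overflow-safe log-sum-exp.  Shift-invariant: adding a constant to
    every score leaves the output unchanged.
    """
    s = np.asarray(scores, dtype=float)
    M = s.shape[-1]
    if M < 2:
        raise ValueError("LLR normalization needs at least 2 subjects")
    out = np.empty_like(s)
    for phi in range(M):
        mask = np.ones(M, dtype=bool)
        mask[phi] = False
        out[..., phi] = s[..., phi] - (logsumexp(s[..., mask], axis=-1) - np.log(M - 1))
    return out


def decide_subject(norm_scores: np.ndarray,
                   theta: np.ndarray) -> Tuple[int, bool]:
    """Identification decision from normalized scores and per-subject thresholds.

    Returns (subject id in 1..M, fallback flag).  The winner is the subject
    with the largest normalized score among those exceeding their threshold;
    if no subject exceeds its threshold the global argmax is returned with
    the fallback flag set.  Ties break toward the lowest subject index.
    """
    s = np.asarray(norm_scores, dtype=float)
    theta = np.asarray(theta, dtype=float)
    above = s > theta
    if above.any():
        masked = np.where(above, s, -np.inf)
        return int(np.argmax(masked)) + 1, False
    return int(np.argmax(s)) + 1, True


def predict_identity(scores: np.ndarray, w: np.ndarray,
                     theta: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Batch identification: (T, N, M) scores -> (labels 1..M, fallback flags)."""
    shat = llr_normalize(fuse_scores(scores, w))
    above = shat > theta[None, :]
    masked = np.where(above, shat, -np.inf)
    fallback = ~above.any(axis=1)
    picks = np.where(fallback, np.argmax(shat, axis=1), np.argmax(masked, axis=1))
    return picks + 1, fallback


# ---------------------------------------------------------------------------
# Threshold learning
# ---------------------------------------------------------------------------

def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Classify-all-negative extreme, midpoints of successive ranked values,
    and an all-positive extreme."""
    v = np.unique(values)
    cands = [v[0] - 1.0]
    if v.size > 1:
        cands.extend((v[:-1] + v[1:]) / 2.0)
    cands.append(v[-1] + 1.0)
    return np.asarray(cands)


def optimal_threshold(measures: np.ndarray,
                      labels: np.ndarray) -> Tuple[float, int]:
    """Minimum-error threshold on a discriminative measure.

    ``labels`` are booleans (True = positive).  A sample is classified
    positive when its measure is <= the threshold (small measures mean
    strong positive evidence).  All candidate thresholds -- the
    classify-all-negative extreme and every midpoint of successive ranked
    measures -- are scanned; returns the (smallest, on ties) threshold
    minimizing the error count, together with that count.
    """
    m = np.asarray(measures, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if m.size == 0:
        raise ValueError("no samples to threshold")
    cands = _candidate_thresholds(m)
    errors = np.array([(np.sum((m <= th) != y)) for th in cands])
    best = int(np.argmin(errors))  # argmin takes the first = smallest threshold
    return float(cands[best]), int(errors[best])


def learn_thresholds(norm_scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-subject detection thresholds minimizing validation error.

    For each subject phi a one-vs-rest threshold on LLR_phi is scanned
    (positive when LLR_phi > theta_phi).  Every subject must contribute at
    least one validation segment.
    """
    s = np.asarray(norm_scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    T, M = s.shape
    theta = np.empty(M)
    for phi in range(M):
        pos = labels == phi + 1
        if not pos.any():
            raise ValueError(f"subject {phi + 1} has no validation segments")
        # scan on the negated score so that 'measure <= thresh' = 'score >= -thresh'
        th, _ = optimal_threshold(-s[:, phi], pos)
        theta[phi] = -th
    return theta


# ---------------------------------------------------------------------------
# MESF
# ---------------------------------------------------------------------------

def theta_requirement(S_row: np.ndarray, w: np.ndarray, theta_phi: float,
                      i: int, phi: int) -> float:
    """Weight value at which a segment crosses the subject-phi decision boundary.

    Evaluates Theta_{i,phi}(x) = C(x) / S_{i,phi}(x) with all weights other
    than w_{i,phi} fixed.  A zero S_{i,phi} makes the boundary independent of
    the weight and raises an error (such segments are excluded from ranking).
    """
    S_row = np.asarray(S_row, dtype=float)
    w = np.asarray(w, dtype=float)
    s = S_row[i, phi]
    if s == 0:
        raise ValueError("S_{i,phi} = 0: decision is independent of w_{i,phi}")
    w0 = w.copy()
    w0[i, phi] = 0.0
    score0 = fuse_scores(S_row, w0)
    M = score0.shape[-1]
    mask = np.ones(M, dtype=bool)
    mask[phi] = False
    competitor = logsumexp(score0[mask]) - np.log(M - 1)
    C = theta_phi + competitor - score0[phi]
    return float(C / s)


def ovr_error_count(norm_scores: np.ndarray, labels: np.ndarray,
                    theta: np.ndarray) -> int:
    """Total one-vs-rest detection errors over all segments and subjects."""
    s = np.asarray(norm_scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    M = s.shape[1]
    pos = s > np.asarray(theta)[None, :]
    truth = labels[:, None] == np.arange(1, M + 1)[None, :]
    return int(np.sum(pos != truth))


def identification_error_count(norm_scores: np.ndarray, labels: np.ndarray,
                               theta: np.ndarray) -> int:
    """Misidentified segments under the thresholded-argmax decision rule."""
    s = np.asarray(norm_scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    above = s > np.asarray(theta)[None, :]
    masked = np.where(above, s, -np.inf)
    fallback = ~above.any(axis=1)
    picks = np.where(fallback, np.argmax(s, axis=1), np.argmax(masked, axis=1))
    return int(np.sum(picks + 1 != labels))


def _excl_logmeanexp(score: np.ndarray, phi: int) -> np.ndarray:
    M = score.shape[-1]
    mask = np.ones(M, dtype=bool)
    mask[phi] = False
    return logsumexp(score[..., mask], axis=-1) - np.log(M - 1)


def mesf_learn(scores: ScoreTensor, theta: np.ndarray,
               max_passes: int = 50) -> FusionWeights:
    """Iterative minimum-error learning of the subject-dependent fusion weights.

    Weights start at one (the SUM fusion).  In fixed lexicographic order
    (model index ascending, then subject index ascending) each weight is
    zeroed, the boundary-crossing measures Theta_{i,phi} of the segments
    whose subject-phi decision the weight can still change are ranked, and
    the weight is re-set to the candidate value (threshold-scan midpoints,
    zero, the previous value, or one past the largest Theta) that minimizes
    the fused identification error on the training segments; the previous
    value is always among the candidates, so the recorded per-update error
    trace is non-increasing.  Full passes repeat until one yields no
    reduction or the pass cap is hit.
    """
    S = scores.scores
    labels = scores.labels
    T, N, M = S.shape
    theta = np.asarray(theta, dtype=float)
    w = np.ones((N, M))
    if np.ptp(S) == 0:
        warnings.warn("degenerate score tensor (all entries identical); "
                      "returning the initial unit weights")
        trace = [identification_error_count(llr_normalize(fuse_scores(S, w)),
                                            labels, theta)]
        return FusionWeights(w=w, theta=theta, error_trace=trace)

    current = identification_error_count(llr_normalize(fuse_scores(S, w)),
                                         labels, theta)
    trace = [current]
    for _ in range(max_passes):
        error_at_pass_start = current
        for i in range(N):
            for phi in range(M):
                w_old = w[i, phi]
                w[i, phi] = 0.0
                score0 = fuse_scores(S, w)  # (T, M); excludes w_{i,phi}
                C = theta[phi] + _excl_logmeanexp(score0, phi) - score0[:, phi]
                s = S[:, i, phi]
                # marking per the algorithm: segments already decided positive
                # at w = 0 (phi members correctly accepted, non-members falsely
                # accepted) leave the scan; the unmarked remainder defines the
                # Theta_{i,phi} = C / S_{i,phi} ranking (decision boundary:
                # positive iff w * S_{i,phi} > C)
                unmarked = ~(C < 0)
                with np.errstate(divide="ignore", invalid="ignore"):
                    crit = np.where(s != 0, C / s, np.nan)[unmarked]
                crit = np.unique(crit[np.isfinite(crit) & (crit >= 0)])
                cands = [0.0, w_old]
                if crit.size:
                    cands.extend((crit[:-1] + crit[1:]) / 2.0)
                    cands.append(crit[-1] + 1.0)
                    cands.extend(crit)  # boundary values themselves (> is strict)
                cands = np.unique(np.asarray(cands))
                # the weight also shifts every other subject's LLR through the
                # competitor average, so candidates are scored by the exact
                # fused identification error; w_old is a candidate, hence the
                # trace cannot increase
                errs = np.empty(len(cands), dtype=int)
                sc = score0.copy()
                for ci, cand in enumerate(cands):
                    sc[:, phi] = score0[:, phi] + cand * s
                    errs[ci] = identification_error_count(llr_normalize(sc),
                                                          labels, theta)
                best = int(np.argmin(errs))  # first minimum = smallest weight
                w[i, phi] = float(cands[best])
                current = int(errs[best])
                trace.append(current)
        if current >= error_at_pass_start:
            break
    return FusionWeights(w=w, theta=theta, error_trace=trace)


# ---------------------------------------------------------------------------
# SVM comparator
# ---------------------------------------------------------------------------

def svm_fusion_train(scores: ScoreTensor, C: float = 100.0) -> SvmFusionModel:
    """One linear maximum-margin classifier per subject, one-vs-rest.

    The N x M score matrix of each segment is concatenated into a single
    feature vector.  ``C`` is large by default so separable score sets are
    separated exactly.
    """
    T, N, M = scores.scores.shape
    X = scores.scores.reshape(T, N * M)
    classifiers = []
    for phi in range(1, M + 1):
        y = (scores.labels == phi).astype(int)
        if y.sum() < 2:
            raise ValueError(f"subject {phi} needs >= 2 training segments")
        clf = SVC(kernel="linear", C=C)
        clf.fit(X, y)
        classifiers.append(clf)
    return SvmFusionModel(classifiers=classifiers, n_models=N, n_subjects=M)


def svm_fusion_apply(model: SvmFusionModel, S: np.ndarray) -> np.ndarray:
    """Per-subject SVM decision values for one (N, M) row or a (T, N, M) stack."""
    S = np.asarray(S, dtype=float)
    single = S.ndim == 2
    if single:
        S = S[None]
    X = S.reshape(S.shape[0], model.n_models * model.n_subjects)
    out = np.stack([clf.decision_function(X) for clf in model.classifiers], axis=1)
    return out[0] if single else out
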