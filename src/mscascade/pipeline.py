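"""Leakage-free LOSO evaluation of the two-stage diagnostic cascade.

Stage 1 screens dementia (AD or FTD) against healthy controls on fused
alpha + delta soft microstate sequences; Stage 2 differentiates AD from
FTD on fused delta + theta sequences, restricted to patients.  Every
fold holds out one subject entirely: microstate templates are clustered
from the training subjects' GFP-peak maps only, the remaining subjects
are split 8:2 (stratified) into training and validation sets, and the
held-out subject's epochs are predicted and aggregated by majority
vote.  An audit log records exactly whose data entered each fold.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .io_core import BANDS, Recording, bandpass, epoch, rereference_average
from .microstate import (
    CLASS_LABELS,
    FusedEpoch,
    TemplateSet,
    align_bands,
    backfit_soft,
    detect_gfp_peaks,
    fuse_bands,
    gfp,
    label_canonical,
    modified_kmeans,
)
from .nn import ModelConfig, TrainConfig, build_model, predict_epochs, train_model

logger = logging.getLogger(__name__)

__all__ = [
    "FoldSplit",
    "SubjectPrediction",
    "MetricReport",
    "StageConfig",
    "SubjectFeatures",
    "prepare_subject",
    "make_loso_splits",
    "majority_vote",
    "balanced_accuracy",
    "roc_auc_youden",
    "run_stage",
    "cascade_predict",
    "run_cascade",
]

STAGE_BANDS = {"stage1": ("alpha", "delta"), "stage2": ("delta", "theta")}
#: class coding per stage; index 1 is the disease-positive class
STAGE_CLASSES = {"stage1": ("HC", "dementia"), "stage2": ("AD", "FTD")}


@dataclass(frozen=True)
class FoldSplit:
    test_subject: str
    train_subjects: tuple[str, ...]
    val_subjects: tuple[str, ...]

    def __post_init__(self) -> None:
        s = {self.test_subject}, set(self.train_subjects), set(self.val_subjects)
        if (s[0] & s[1]) or (s[0] & s[2]) or (s[1] & s[2]):
            raise ValueError("fold subject sets overlap")


@dataclass
class SubjectPrediction:
    subject_id: str
    true_label: str
    epoch_votes: np.ndarray
    epoch_probs: np.ndarray  # (n_epochs, n_classes)
    final_label: str
    mean_prob: np.ndarray


@dataclass
class MetricReport:
    classes: tuple[str, ...]
    confusion: np.ndarray
    balanced_accuracy: float
    recalls: dict[str, float]
    auc: float | None = None
    youden_threshold: float | None = None
    statistics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class StageConfig:
    """Knobs for one LOSO stage run (model, training, clustering)."""

    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    kmeans_restarts: int = 10
    window_s: float = 10.0
    step_s: float = 5.0
    #: threshold epoch votes at the fold's validation Youden point rather
    #: than a fixed 0.5.  A classifier trained on a leave-one-subject-out
    #: fold carries a small constant bias tied to the fold's class
    #: composition (the held-out subject's class is the training
    #: minority); on weakly separable data majority voting amplifies that
    #: bias into systematic subject-level decisions.  Calibrating the
    #: threshold on the held-out validation epochs absorbs the constant
    #: without touching test data.
    calibrate_votes: bool = True

    @classmethod
    def small(cls, max_epochs: int = 25, patience: int = 8) -> "StageConfig":
        """Reduced desk-scale configuration: narrow model, short training.

        Suitable for cohorts of around a dozen subjects with strong
        simulated effects; the full-size defaults are meant for real
        cohorts on substantially more compute.
        """
        return cls(
            model=ModelConfig(stem_width=8, block_widths=(8, 16), attn_embed=16, attn_heads=4),
            train=TrainConfig(lr=3e-3, max_epochs=max_epochs, patience=patience, seed=42),
            kmeans_restarts=5,
        )


# ---------------------------------------------------------------------------
# per-subject feature preparation (done once, reused across folds)


@dataclass
class SubjectFeatures:
    """Band-filtered epochs and pooled GFP-peak maps for one subject."""

    subject_id: str
    group: str
    rate: float
    band_epochs: dict[str, np.ndarray]  # band -> (n_epochs, C, T)
    peak_maps: dict[str, np.ndarray]  # band -> (n_peaks, C)


def prepare_subject(
    rec: Recording,
    bands: tuple[str, ...],
    window_s: float = 10.0,
    step_s: float = 5.0,
) -> SubjectFeatures:
    """Re-reference, band-filter, epoch and collect GFP-peak topographies."""
    rec = rereference_average(rec)
    band_epochs: dict[str, np.ndarray] = {}
    peaks: dict[str, np.ndarray] = {}
    for band in bands:
        filt = bandpass(rec, BANDS[band])
        es = epoch(filt, window_s, step_s, band=band)
        arr = np.stack(es.epochs) if len(es) else np.zeros((0, rec.n_channels, 0))
        band_epochs[band] = arr
        maps = []
        for ep in es.epochs:
            g = gfp(ep)
            idx = detect_gfp_peaks(g)
            maps.append(ep[:, idx].T)
        peaks[band] = np.vstack(maps) if maps else np.zeros((0, rec.n_channels))
    return SubjectFeatures(rec.subject_id, rec.group, rec.rate, band_epochs, peaks)


# ---------------------------------------------------------------------------
# splits, voting, metrics


def make_loso_splits(subjects: dict[str, str], seed: int = 42, val_fraction: float = 0.2) -> list[FoldSplit]:
    """One fold per subject with a stratified subject-level 8:2 train/val split.

    ``subjects`` maps subject_id -> class label.  Classes with a single
    remaining subject cannot be stratified; they go to training with a
    warning.
    """
    ids = sorted(subjects)
    if len(ids) < 3 or len(set(subjects.values())) < 2:
        raise ValueError("need at least 3 subjects and 2 classes")
    folds = []
    for i, test in enumerate(ids):
        rng = np.random.default_rng([seed, i])
        rest = [s for s in ids if s != test]
        by_class: dict[str, list[str]] = {}
        for s in rest:
            by_class.setdefault(subjects[s], []).append(s)
        train, val = [], []
        for cls in sorted(by_class):
            members = by_class[cls]
            if len(members) < 2:
                warnings.warn(
                    f"class {cls} has a single subject in fold {test}; skipping stratified "
                    "validation for it",
                    stacklevel=2,
                )
                train.extend(members)
                continue
            perm = list(rng.permutation(members))
            n_val = max(1, int(round(val_fraction * len(members))))
            n_val = min(n_val, len(members) - 1)
            val.extend(perm[:n_val])
            train.extend(perm[n_val:])
        folds.append(FoldSplit(test, tuple(sorted(train)), tuple(sorted(val))))
    return folds


def majority_vote(
    epoch_votes: np.ndarray, epoch_probs: np.ndarray | None = None, positive_class: int = 1
) -> int:
    """Subject label as the modal epoch vote.

    Ties are broken by the higher mean predicted probability; a residual
    exact tie goes to the disease-positive class.
    """
    votes = np.asarray(epoch_votes)
    if votes.size == 0:
        raise ValueError("no epoch votes")
    counts = Counter(votes.tolist())
    top = max(counts.values())
    leaders = sorted(c for c, n in counts.items() if n == top)
    if len(leaders) == 1:
        return int(leaders[0])
    if epoch_probs is not None:
        means = {c: float(np.mean(np.asarray(epoch_probs)[:, c])) for c in leaders}
        best = max(means.values())
        leaders = sorted(c for c, m in means.items() if m == best)
        if len(leaders) == 1:
            return int(leaders[0])
    return int(positive_class if positive_class in leaders else leaders[0])


def balanced_accuracy(confusion: np.ndarray) -> float:
    """Arithmetic mean of per-class recalls from a confusion matrix."""
    c = np.asarray(confusion, dtype=float)
    row = c.sum(axis=1)
    if np.any(row == 0):
        raise ValueError("every true class needs at least one subject")
    return float(np.mean(np.diag(c) / row))


def roc_auc_youden(scores, labels) -> tuple[float, float]:
    """Rank-statistic AUC and the Youden-optimal operating threshold.

    AUC uses midranks (ties averaged).  The threshold maximizes
    J = sensitivity + specificity − 1 over the observed scores; ties in
    J break toward the higher-sensitivity operating point.
    """
    from scipy.stats import rankdata

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    r = rankdata(s)
    auc = (r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1)

    best_j, best_thr, best_sens = -np.inf, None, -np.inf
    for thr in np.unique(s):
        pred = s >= thr
        sens = np.sum(pred & (y == 1)) / n1
        spec = np.sum(~pred & (y == 0)) / n0
        j = sens + spec - 1.0
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and sens > best_sens):
            best_j, best_thr, best_sens = j, float(thr), sens
    return float(auc), best_thr


def _confusion(true_idx: np.ndarray, pred_idx: np.ndarray, k: int) -> np.ndarray:
    c = np.zeros((k, k), dtype=int)
    for t, p in zip(true_idx, pred_idx):
        c[t, p] += 1
    return c


def _report(classes, true_idx, pred_idx, scores=None, true_binary=None) -> MetricReport:
    k = len(classes)
    conf = _confusion(np.asarray(true_idx), np.asarray(pred_idx), k)
    recalls = {
        classes[i]: float(conf[i, i] / conf[i].sum()) if conf[i].sum() else float("nan")
        for i in range(k)
    }
    bal = balanced_accuracy(conf)
    auc = thr = None
    if scores is not None and k == 2:
        auc, thr = roc_auc_youden(scores, true_binary)
    return MetricReport(tuple(classes), conf, bal, recalls, auc, thr)


# ---------------------------------------------------------------------------
# the LOSO stage runner


def _stage_label(group: str, stage: str) -> int | None:
    if stage == "stage1":
        return 0 if group == "HC" else 1
    if stage == "stage2":
        return {"AD": 0, "FTD": 1}.get(group)
    raise ValueError(f"unknown stage {stage!r}")


def _fold_templates(
    subjects: dict[str, SubjectFeatures],
    allow: tuple[str, ...],
    bands: tuple[str, str],
    restarts: int,
    seed: int,
) -> dict[str, TemplateSet]:
    """Cluster pooled GFP-peak maps of the allow-listed subjects per band.

    The broadband set anchors canonical A–D letters; each narrow band is
    Hungarian-aligned to it.  Touching any subject outside ``allow`` is
    impossible by construction.
    """
    out: dict[str, TemplateSet] = {}
    pooled_bb = np.vstack([subjects[s].peak_maps["broadband"] for s in allow])
    anchor = label_canonical(
        modified_kmeans(pooled_bb, n_restarts=restarts, seed=np.random.default_rng(seed), band="broadband")
    )
    out["broadband"] = anchor
    for band in bands:
        pooled = np.vstack([subjects[s].peak_maps[band] for s in allow])
        ts = modified_kmeans(pooled, n_restarts=restarts, seed=np.random.default_rng(seed + 1), band=band)
        out[band] = align_bands(ts, anchor)
    return out


def _fused_for_subject(
    feats: SubjectFeatures, templates: dict[str, TemplateSet], bands: tuple[str, str], stage: str
) -> np.ndarray:
    """All epochs of one subject backfit against fold templates and fused."""
    fused = []
    n_ep = feats.band_epochs[bands[0]].shape[0]
    for i in range(n_ep):
        seqs = [
            backfit_soft(feats.band_epochs[b][i], templates[b], feats.subject_id, i)
            for b in bands
        ]
        fused.append(fuse_bands(seqs[0], seqs[1], stage).values)
    return np.asarray(fused, dtype=np.float32)


def run_stage(
    stage: str,
    subjects: list[SubjectFeatures],
    config: StageConfig | None = None,
    seed: int = 42,
    folds: list[FoldSplit] | None = None,
) -> tuple[list[SubjectPrediction], MetricReport, list[dict]]:
    """Full LOSO evaluation of one cascade stage.

    Returns per-subject predictions, the aggregate metric report, and the
    audit log (one entry per fold listing every subject whose data was
    used for templates, training and validation).
    """
    if stage not in STAGE_BANDS:
        raise ValueError(f"stage must be one of {tuple(STAGE_BANDS)}")
    config = config or StageConfig()
    bands = STAGE_BANDS[stage]
    feats = {s.subject_id: s for s in subjects if _stage_label(s.group, stage) is not None}
    for s in feats.values():
        missing = [b for b in (*bands, "broadband") if b not in s.band_epochs]
        if missing:
            raise ValueError(f"subject {s.subject_id} lacks bands {missing} for {stage}")
    labels = {sid: _stage_label(s.group, stage) for sid, s in feats.items()}
    if folds is None:
        folds = make_loso_splits({sid: str(v) for sid, v in labels.items()}, seed=seed)

    # cohort-level inverse-frequency loss weights, constant across folds:
    # re-deriving them per fold would over-weight the class the held-out
    # subject came from and bias every fold toward its own class
    from .nn import class_weights as _cw

    cohort_counts = np.bincount(list(labels.values()), minlength=config.model.n_classes)
    loss_weights = _cw(np.maximum(cohort_counts, 1))

    preds: list[SubjectPrediction] = []
    audit: list[dict] = []
    for fold_i, fold in enumerate(folds):
        templates = _fold_templates(feats, fold.train_subjects, bands, config.kmeans_restarts, seed + fold_i)
        fused = {
            sid: _fused_for_subject(feats[sid], templates, bands, stage)
            for sid in (*fold.train_subjects, *fold.val_subjects, fold.test_subject)
        }
        tx = np.concatenate([fused[s] for s in fold.train_subjects])
        ty = np.concatenate([[labels[s]] * len(fused[s]) for s in fold.train_subjects]).astype(int)
        vx = np.concatenate([fused[s] for s in fold.val_subjects])
        vy = np.concatenate([[labels[s]] * len(fused[s]) for s in fold.val_subjects]).astype(int)
        t_sub = [s for s in fold.train_subjects for _ in range(len(fused[s]))]
        v_sub = [s for s in fold.val_subjects for _ in range(len(fused[s]))]

        model = build_model(config.model, seed=config.train.seed)
        train_model(model, tx, ty, vx, vy, config.train,
                    train_subjects=t_sub, val_subjects=v_sub, loss_weights=loss_weights)
        threshold = _fold_threshold(model, vx, vy, config)
        probs = predict_epochs(model, fused[fold.test_subject], config.train.batch_size)
        votes = (probs[:, 1] >= threshold).astype(int)
        final = majority_vote(votes, probs, positive_class=1)
        preds.append(
            SubjectPrediction(
                subject_id=fold.test_subject,
                true_label=STAGE_CLASSES[stage][labels[fold.test_subject]],
                epoch_votes=votes,
                epoch_probs=probs,
                final_label=STAGE_CLASSES[stage][final],
                mean_prob=probs.mean(axis=0),
            )
        )
        audit.append(
            {
                "stage": stage,
                "fold": fold_i,
                "test_subject": fold.test_subject,
                "template_subjects": sorted(fold.train_subjects),
                "train_subjects": sorted(set(t_sub)),
                "val_subjects": sorted(set(v_sub)),
            }
        )
        logger.info(
            "%s fold %d: test %s true %s pred %s",
            stage, fold_i, fold.test_subject,
            preds[-1].true_label, preds[-1].final_label,
        )

    classes = STAGE_CLASSES[stage]
    true_idx = [classes.index(p.true_label) for p in preds]
    pred_idx = [classes.index(p.final_label) for p in preds]
    scores = [p.mean_prob[1] for p in preds]
    report = _report(classes, true_idx, pred_idx, scores, np.asarray(true_idx))
    return preds, report, audit


def _fold_threshold(model, vx: np.ndarray, vy: np.ndarray, config: StageConfig) -> float:
    """Epoch-vote threshold for one fold.

    The midpoint between the median validation scores of the two classes:
    under class separation it sits centrally between the clusters, and on
    uninformative data it tracks (and thereby cancels) the fold's
    constant output bias.  Falls back to 0.5 when calibration is off or
    the validation set is single-class.
    """
    if not config.calibrate_votes or len(np.unique(vy)) < 2:
        return 0.5
    scores = predict_epochs(model, vx, config.train.batch_size)[:, 1]
    med_pos = float(np.median(scores[vy == 1]))
    med_neg = float(np.median(scores[vy == 0]))
    return (med_pos + med_neg) / 2.0


# ---------------------------------------------------------------------------
# cascade composition


def cascade_predict(stage1_label: str, stage2_label: str | None) -> str:
    """Compose the two binary decisions into a 3-class label."""
    if stage1_label == "HC":
        return "HC"
    if stage1_label == "dementia":
        if stage2_label not in ("AD", "FTD"):
            raise ValueError("stage-2 label required for a dementia call")
        return stage2_label
    raise ValueError(f"unexpected stage-1 label {stage1_label!r}")


def run_cascade(
    subjects: list[SubjectFeatures],
    stage1_config: StageConfig | None = None,
    stage2_config: StageConfig | None = None,
    seed: int = 42,
) -> dict:
    """Run both LOSO stages and compose subject-level 3-class predictions.

    Stage 2 is evaluated LOSO on the true patients.  For subjects the
    screening stage falsely flags as dementia, a fallback stage-2 model
    trained on all patients supplies the subtype call (no leakage: such
    subjects never appear in stage-2 training data).
    """
    stage1_config = stage1_config or StageConfig()
    stage2_config = stage2_config or stage1_config
    p1, r1, audit1 = run_stage("stage1", subjects, stage1_config, seed)
    p2, r2, audit2 = run_stage("stage2", subjects, stage2_config, seed)
    s1 = {p.subject_id: p.final_label for p in p1}
    s2 = {p.subject_id: p.final_label for p in p2}

    fallback_needed = [sid for sid, lbl in s1.items() if lbl == "dementia" and sid not in s2]
    if fallback_needed:
        s2.update(_fallback_stage2(subjects, fallback_needed, stage2_config, seed))

    groups = {s.subject_id: s.group for s in subjects}
    classes = ("AD", "FTD", "HC")
    true_idx, pred_idx, composed = [], [], {}
    for sid in sorted(groups):
        label = cascade_predict(s1[sid], s2.get(sid))
        composed[sid] = label
        true_idx.append(classes.index(groups[sid]))
        pred_idx.append(classes.index(label))
    report3 = _report(classes, true_idx, pred_idx)
    return {
        "stage1": {"predictions": p1, "report": r1, "audit": audit1},
        "stage2": {"predictions": p2, "report": r2, "audit": audit2},
        "composed": composed,
        "report": report3,
    }


def run_synthetic_benchmark(
    cohort_seed: int = 7,
    n_per_class: dict[str, int] | None = None,
    duration_s: float = 35.0,
    stage_config: StageConfig | None = None,
    run_seed: int = 1,
    spec: "CohortSpec | None" = None,
) -> dict:
    """Simulate a cohort and run the full two-stage LOSO cascade on it.

    The desk-scale smoke benchmark: a 12-subject strong-effect cohort
    (35 s per subject) with the reduced model configuration.  Returns the
    :func:`run_cascade` result dict augmented with the cohort spec.
    """
    from .synthetic import CohortSpec, simulate_cohort

    if spec is None:
        spec = CohortSpec(
            n_per_class=n_per_class or {"AD": 4, "FTD": 4, "HC": 4},
            duration_s=duration_s,
            seed=cohort_seed,
        )
    cohort = simulate_cohort(spec)
    bands = ("broadband", "alpha", "delta", "theta")
    feats = [prepare_subject(rec, bands) for rec, _ in cohort]
    config = stage_config or StageConfig.small()
    result = run_cascade(feats, config, config, seed=run_seed)
    result["spec"] = spec
    result["groups"] = {f.subject_id: f.group for f in feats}
    return result


def _fallback_stage2(
    subjects: list[SubjectFeatures],
    targets: list[str],
    config: StageConfig,
    seed: int,
) -> dict[str, str]:
    """Subtype calls for screening false positives from an all-patient model."""
    feats = {s.subject_id: s for s in subjects}
    patients = {sid: s for sid, s in feats.items() if s.group in ("AD", "FTD")}
    labels = {sid: _stage_label(s.group, "stage2") for sid, s in patients.items()}
    bands = STAGE_BANDS["stage2"]
    ids = sorted(patients)
    rng = np.random.default_rng([seed, 999])
    by_class: dict[int, list[str]] = {}
    for sid in ids:
        by_class.setdefault(labels[sid], []).append(sid)
    train, val = [], []
    for cls in sorted(by_class):
        perm = list(rng.permutation(by_class[cls]))
        n_val = max(1, int(round(0.2 * len(perm))))
        val.extend(perm[:n_val])
        train.extend(perm[n_val:])
    templates = _fold_templates(patients, tuple(train), bands, config.kmeans_restarts, seed)
    fused = {sid: _fused_for_subject(feats[sid], templates, bands, "stage2") for sid in (*train, *val, *targets)}
    tx = np.concatenate([fused[s] for s in train])
    ty = np.concatenate([[labels[s]] * len(fused[s]) for s in train]).astype(int)
    vx = np.concatenate([fused[s] for s in val])
    vy = np.concatenate([[labels[s]] * len(fused[s]) for s in val]).astype(int)
    counts = np.bincount(list(labels.values()), minlength=2)
    model = build_model(config.model, seed=config.train.seed)
    from .nn import class_weights as _cw

    train_model(model, tx, ty, vx, vy, config.train,
                train_subjects=[s for s in train for _ in range(len(fused[s]))],
                val_subjects=[s for s in val for _ in range(len(fused[s]))],
                loss_weights=_cw(np.maximum(counts, 1)))
    threshold = _fold_threshold(model, vx, vy, config)
    out = {}
    for sid in targets:
        probs = predict_epochs(model, fused[sid], config.train.batch_size)
        votes = (probs[:, 1] >= threshold).astype(int)
        out[sid] = STAGE_CLASSES["stage2"][majority_vote(votes, probs, positive_class=1)]
    return out
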