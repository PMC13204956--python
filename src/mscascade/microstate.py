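"""Multi-band microstate extraction, cross-band alignment and soft backfitting.

The pipeline implemented here:

1. compute global field power (GFP) and keep topographies at its local
   maxima — the moments of highest topographic signal-to-noise;
2. cluster those peak maps with a polarity-invariant modified k-means,
   selecting the restart with the highest global explained variance (GEV);
3. give the broadband templates their canonical A–D letters by matching
   against built-in dipolar prototypes, and relabel each narrowband
   template set against the broadband anchor by minimum-cost bipartite
   (Hungarian) assignment on 1 − |spatial correlation|;
4. backfit templates *softly*: per-sample polarity-invariant correlation
   trajectories r_k(t) ∈ [0, 1] for the four classes instead of
   winner-takes-all labels, and fuse two bands into an 8 × T stage input.

Microstate topographies are sign-agnostic (oscillation phase flips the
map), so every similarity here is an absolute Pearson correlation across
channels unless explicitly requested signed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

__all__ = [
    "CLASS_LABELS",
    "TemplateSet",
    "SoftSequence",
    "FusedEpoch",
    "MicrostateStats",
    "gfp",
    "detect_gfp_peaks",
    "spatial_corr",
    "modified_kmeans",
    "gev",
    "label_canonical",
    "align_bands",
    "backfit_soft",
    "fuse_bands",
    "microstate_stats",
    "save_fused_epochs",
    "load_fused_epochs",
]

CLASS_LABELS = ("A", "B", "C", "D")


@dataclass
class TemplateSet:
    """Four unit-norm, zero-mean microstate maps for one band.

    ``maps`` rows are ordered by ``labels`` position: row i is the map for
    class ``labels[i]``.  ``map_for(label)`` retrieves by letter.
    """

    band: str
    maps: np.ndarray  # (4, n_channels)
    labels: tuple[str, ...]
    gev_total: float = float("nan")
    gev_per_map: np.ndarray | None = None
    n_peak_maps: int = 0
    channels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.shape[0] != len(self.labels):
            raise ValueError("one label per map required")
        if sorted(self.labels) != sorted(CLASS_LABELS[: len(self.labels)]):
            raise ValueError(f"labels must be a permutation of {CLASS_LABELS[: self.maps.shape[0]]}")

    def map_for(self, label: str) -> np.ndarray:
        return self.maps[self.labels.index(label)]

    def in_class_order(self) -> np.ndarray:
        """Maps reordered A, B, C, D."""
        order = [self.labels.index(c) for c in CLASS_LABELS[: self.maps.shape[0]]]
        return self.maps[order]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "band": self.band,
            "labels": list(self.labels),
            "maps": self.maps.tolist(),
            "gev_total": self.gev_total,
            "gev_per_map": None if self.gev_per_map is None else list(map(float, self.gev_per_map)),
            "n_peak_maps": self.n_peak_maps,
            "channels": None if self.channels is None else list(self.channels),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TemplateSet":
        d = json.loads(Path(path).read_text())
        return cls(
            band=d["band"],
            maps=np.asarray(d["maps"], dtype=float),
            labels=tuple(d["labels"]),
            gev_total=d["gev_total"],
            gev_per_map=None if d["gev_per_map"] is None else np.asarray(d["gev_per_map"]),
            n_peak_maps=d["n_peak_maps"],
            channels=None if d["channels"] is None else tuple(d["channels"]),
        )


@dataclass
class SoftSequence:
    """Continuous soft-assignment trajectories for one epoch and band.

    ``values`` is (4, T) in class order A–D; entry (k, t) is the
    polarity-invariant correlation between the instantaneous topography and
    template k.  ``flagged`` marks zero-variance frames emitted as 0.
    """

    band: str
    values: np.ndarray
    subject_id: str
    epoch_index: int
    flagged: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


@dataclass
class FusedEpoch:
    """Two-band stack: rows 0–3 first band's A–D, rows 4–7 second band's."""

    stage: str
    values: np.ndarray  # (8, T)
    label: str
    subject_id: str
    epoch_index: int = 0
    bands: tuple[str, str] = ("", "")


@dataclass
class MicrostateStats:
    occurrence: dict[str, float]
    mean_dwell: dict[str, float]
    coverage: dict[str, float]
    transitions: np.ndarray  # (4, 4) row-normalized
    empty_rows: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# primitives


def gfp(data: np.ndarray) -> np.ndarray | float:
    """Global field power: the spatial standard deviation per sample.

    Accepts a single topography (n_channels,) or a matrix
    (n_channels, T); returns a scalar or a series accordingly.
    """
    arr = np.asarray(data, dtype=float)
    single = arr.ndim == 1
    if single:
        arr = arr[:, None]
    if arr.shape[0] < 2:
        raise ValueError("GFP needs at least 2 channels")
    out = arr.std(axis=0, ddof=0)
    return float(out[0]) if single else out


def detect_gfp_peaks(series: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of a GFP series (endpoints excluded)."""
    s = np.asarray(series, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 samples to find peaks")
    inner = np.arange(1, s.size - 1)
    mask = (s[inner] > s[inner - 1]) & (s[inner] > s[inner + 1])
    return inner[mask]


def spatial_corr(a: np.ndarray, b: np.ndarray, polarity_invariant: bool = True) -> float:
    """Pearson correlation across channels of two mean-removed maps."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("topographies differ in length")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance topography")
    r = float(a @ b / (na * nb))
    return abs(r) if polarity_invariant else r


def _corr_matrix(maps: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """|Pearson| between every map (rows) and every template (rows)."""
    m = maps - maps.mean(axis=1, keepdims=True)
    t = templates - templates.mean(axis=1, keepdims=True)
    m_norm = np.linalg.norm(m, axis=1, keepdims=True)
    t_norm = np.linalg.norm(t, axis=1, keepdims=True)
    m = np.divide(m, m_norm, out=np.zeros_like(m), where=m_norm > 0)
    t = np.divide(t, t_norm, out=np.zeros_like(t), where=t_norm > 0)
    return np.abs(m @ t.T)


def _normalize_map(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("degenerate (constant) map")
    return v / n


# ---------------------------------------------------------------------------
# clustering


def gev(
    templates: "TemplateSet | np.ndarray",
    maps: np.ndarray,
    gfp_values: np.ndarray | None = None,
) -> float:
    """Global explained variance of a template set on a set of maps.

    GEV = Σ_t (GFP_t · ρ_best(t))² / Σ_t GFP_t², where ρ_best(t) is the
    winning template's polarity-invariant correlation with map t.  When
    ``gfp_values`` is omitted it is computed from the maps themselves.
    """
    tmpl = templates.maps if isinstance(templates, TemplateSet) else np.asarray(templates)
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 1:
        maps = maps[None, :]
    g = gfp(maps.T) if gfp_values is None else np.asarray(gfp_values, dtype=float)
    if g.shape[0] != maps.shape[0]:
        raise ValueError("gfp_values and maps misaligned")
    denom = float(np.sum(g**2))
    if denom == 0:
        raise ValueError("all-zero GFP")
    rho = _corr_matrix(maps, tmpl)
    best = rho.max(axis=1)
    return float(np.sum((g * best) ** 2) / denom)


def _gev_per_template(templates: np.ndarray, maps: np.ndarray, g: np.ndarray) -> np.ndarray:
    rho = _corr_matrix(maps, templates)
    assign = rho.argmax(axis=1)
    best = rho.max(axis=1)
    denom = float(np.sum(g**2))
    out = np.zeros(templates.shape[0])
    for k in range(templates.shape[0]):
        sel = assign == k
        out[k] = np.sum((g[sel] * best[sel]) ** 2) / denom
    return out


def modified_kmeans(
    peak_maps: np.ndarray,
    k: int = 4,
    n_restarts: int = 20,
    max_iter: int = 100,
    seed: int | np.random.Generator = 0,
    gev_tol: float = 1e-6,
    band: str = "broadband",
) -> TemplateSet:
    """Polarity-invariant modified k-means over GFP-peak topographies.

    Each map is assigned to the template with the highest absolute spatial
    correlation; each template is updated to the dominant eigenvector of
    the outer-product sum of its assigned maps (the polarity-proof analogue
    of the cluster mean).  Across restarts the solution with the highest
    GEV is kept.  Returned maps are unit-norm and zero-mean, provisionally
    labeled A–D in arbitrary order (use :func:`label_canonical` /
    :func:`align_bands` for meaningful letters).
    """
    maps = np.asarray(peak_maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < k:
        raise ValueError(f"need at least k={k} peak maps, got {maps.shape}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    centered = maps - maps.mean(axis=1, keepdims=True)
    g = centered.std(axis=1, ddof=0)
    norms = np.linalg.norm(centered, axis=1)
    keep = norms > 0
    if not np.all(keep):
        logger.warning("modified_kmeans: dropping %d zero-variance maps", int((~keep).sum()))
        centered, g, norms = centered[keep], g[keep], norms[keep]
        if centered.shape[0] < k:
            raise ValueError("too few non-degenerate maps for clustering")
    unit = centered / norms[:, None]
    if np.allclose(np.abs(unit @ unit[0]), 1.0) and k > 1:
        raise ValueError("all peak maps identical up to sign; k>1 clustering is degenerate")

    best_templates, best_gev = None, -np.inf
    for _ in range(n_restarts):
        idx = rng.choice(unit.shape[0], size=k, replace=False)
        templates = unit[idx].copy()
        assign = np.full(unit.shape[0], -1)
        prev_gev = -np.inf
        for _ in range(max_iter):
            rho = np.abs(unit @ templates.T)
            new_assign = rho.argmax(axis=1)
            for j in range(k):
                sel = new_assign == j
                if not np.any(sel):  # dead cluster: reseed on worst-fit map
                    worst = rho.max(axis=1).argmin()
                    templates[j] = unit[worst]
                    continue
                x = unit[sel]
                s = x.T @ x
                w, v = np.linalg.eigh(s)
                templates[j] = _normalize_map(v[:, -1])
            cur = np.sum((g * np.abs(unit @ templates.T).max(axis=1)) ** 2) / np.sum(g**2)
            if np.array_equal(new_assign, assign) or cur - prev_gev < gev_tol:
                assign = new_assign
                break
            assign, prev_gev = new_assign, cur
        total = float(np.sum((g * np.abs(unit @ templates.T).max(axis=1)) ** 2) / np.sum(g**2))
        if total > best_gev:
            best_gev, best_templates = total, templates.copy()

    per_map = _gev_per_template(best_templates, centered, g)
    return TemplateSet(
        band=band,
        maps=best_templates,
        labels=CLASS_LABELS[:k],
        gev_total=best_gev,
        gev_per_map=per_map,
        n_peak_maps=int(unit.shape[0]),
    )


# ---------------------------------------------------------------------------
# labeling and alignment


def _hungarian_relabel(moving: TemplateSet, anchor_maps: np.ndarray, anchor_labels: tuple[str, ...]) -> tuple[TemplateSet, float]:
    c = _corr_matrix(moving.maps, anchor_maps)  # (4 moving, 4 anchor)
    cost = 1.0 - c
    rows, cols = linear_sum_assignment(cost)
    labels = [""] * moving.maps.shape[0]
    for r, col in zip(rows, cols):
        labels[r] = anchor_labels[col]
    total = float(cost[rows, cols].sum())
    out = TemplateSet(
        band=moving.band,
        maps=moving.maps.copy(),
        labels=tuple(labels),
        gev_total=moving.gev_total,
        gev_per_map=moving.gev_per_map,
        n_peak_maps=moving.n_peak_maps,
        channels=moving.channels,
    )
    return out, total


def label_canonical(broadband: TemplateSet, prototypes: np.ndarray | None = None) -> TemplateSet:
    """Assign canonical A–D letters to broadband templates.

    Letters come from minimum-cost bipartite matching of 1 − |ρ| against
    the built-in dipolar prototypes for the bundled 10–20 montage (class A:
    right-anterior/left-posterior diagonal, B: the mirrored diagonal, C:
    anterior–posterior midline, D: posterior-focal).  The matching
    mechanism is identical to the cross-band alignment.
    """
    if prototypes is None:
        from .synthetic import make_prototypes
        from .montage import standard_1020_19

        prototypes = np.stack([p.map for p in make_prototypes(standard_1020_19())])
    out, cost = _hungarian_relabel(broadband, np.asarray(prototypes), CLASS_LABELS)
    logger.info("canonical labeling of broadband templates: total cost %.4f", cost)
    return out


def align_bands(narrow: TemplateSet, anchor: TemplateSet) -> TemplateSet:
    """Relabel a narrowband template set against the broadband anchor.

    Builds C = |ρ(S_j, B_k)|, the absolute spatial correlation between each
    narrowband template S_j and anchor template B_k, and solves the
    minimum-cost one-to-one assignment on D = 1 − C with the Hungarian
    algorithm so class letters keep one physiological meaning across bands.
    """
    if narrow.maps.shape[1] != anchor.maps.shape[1]:
        raise ValueError("montage mismatch between template sets")
    out, cost = _hungarian_relabel(narrow, anchor.maps, anchor.labels)
    logger.debug("aligned %s to %s anchor, cost %.4f", narrow.band, anchor.band, cost)
    return out


# ---------------------------------------------------------------------------
# backfitting and fusion


def backfit_soft(
    epoch_data: np.ndarray,
    templates: TemplateSet,
    subject_id: str = "",
    epoch_index: int = 0,
    polarity_invariant: bool = True,
) -> SoftSequence:
    """Continuous soft backfitting of one epoch against four templates.

    r_k(t) = |ρ(x(t), m_k)| per sample, rows in class order A–D — no
    winner-takes-all discretization.  Zero-variance frames (flat
    topography) have undefined correlation; they are emitted as 0 and their
    indices flagged.
    """
    x = np.asarray(epoch_data, dtype=float)
    if x.shape[0] != templates.maps.shape[1]:
        raise ValueError("epoch channel count does not match template montage")
    xc = x - x.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(xc, axis=0)
    ok = norms > 0
    safe = np.where(ok, norms, 1.0)
    tmpl = templates.in_class_order()
    tc = tmpl - tmpl.mean(axis=1, keepdims=True)
    tc = tc / np.linalg.norm(tc, axis=1, keepdims=True)
    vals = (tc @ xc) / safe[None, :]
    if polarity_invariant:
        vals = np.abs(vals)
    vals[:, ~ok] = 0.0
    return SoftSequence(
        band=templates.band,
        values=vals,
        subject_id=subject_id,
        epoch_index=epoch_index,
        flagged=np.flatnonzero(~ok),
    )


def fuse_bands(first: SoftSequence, second: SoftSequence, stage: str) -> FusedEpoch:
    """Stack two soft sequences into the 8 × T stage input.

    Rows 0–3 are the first band's classes A–D, rows 4–7 the second band's.
    Values are carried over unchanged.
    """
    if first.values.shape != second.values.shape:
        raise ValueError("soft sequences differ in shape")
    if first.subject_id != second.subject_id or first.epoch_index != second.epoch_index:
        raise ValueError("soft sequences come from different epochs/subjects")
    values = np.vstack([first.values, second.values])
    return FusedEpoch(
        stage=stage,
        values=values,
        label="",
        subject_id=first.subject_id,
        epoch_index=first.epoch_index,
        bands=(first.band, second.band),
    )


def save_fused_epochs(path: str | Path, epochs: list[FusedEpoch]) -> None:
    """Store fused epochs as a compressed array container with a manifest."""
    manifest = [
        {"stage": e.stage, "label": e.label, "subject_id": e.subject_id,
         "epoch_index": e.epoch_index, "bands": list(e.bands)}
        for e in epochs
    ]
    np.savez_compressed(
        path,
        values=np.stack([e.values for e in epochs]),
        manifest=json.dumps(manifest),
    )


def load_fused_epochs(path: str | Path) -> list[FusedEpoch]:
    with np.load(path, allow_pickle=False) as data:
        values = data["values"]
        manifest = json.loads(str(data["manifest"]))
    return [
        FusedEpoch(values=values[i], bands=tuple(m.pop("bands")), **m)
        for i, m in enumerate(manifest)
    ]


# ---------------------------------------------------------------------------
# descriptive statistics


def microstate_stats(seq: SoftSequence | np.ndarray, rate: float) -> MicrostateStats:
    """Classical microstate statistics from an argmax-discretized sequence.

    The soft sequence is discretized per sample by argmax; consecutive
    equal labels merge into segments.  Coverage is the sample share per
    class, mean dwell the mean segment length in ms, occurrence the number
    of segments per second, and transitions the row-normalized counts
    between consecutive *distinct* segments.  Classes with no outgoing
    transition get an all-zero row and are flagged in ``empty_rows``.
    """
    values = seq.values if isinstance(seq, SoftSequence) else np.asarray(seq)
    if values.shape[1] < 2:
        raise ValueError("sequence too short")
    k = values.shape[0]
    labels = values.argmax(axis=0)
    t = values.shape[1]
    duration_s = t / rate

    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [t]))
    seg_labels = labels[starts]
    seg_lens = ends - starts

    coverage = {c: float(np.sum(labels == i) / t) for i, c in enumerate(CLASS_LABELS[:k])}
    occurrence, mean_dwell = {}, {}
    for i, c in enumerate(CLASS_LABELS[:k]):
        sel = seg_labels == i
        occurrence[c] = float(np.sum(sel) / duration_s)
        mean_dwell[c] = float(seg_lens[sel].mean() / rate * 1000.0) if np.any(sel) else 0.0

    counts = np.zeros((k, k))
    for a, b in zip(seg_labels[:-1], seg_labels[1:]):
        counts[a, b] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    trans = np.divide(counts, row_sums, out=np.zeros_like(counts), where=row_sums > 0)
    empty = tuple(CLASS_LABELS[i] for i in range(k) if row_sums[i, 0] == 0)
    return MicrostateStats(occurrence, mean_dwell, coverage, trans, empty)
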