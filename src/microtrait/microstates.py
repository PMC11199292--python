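"""Microstate segmentation: GFP peaks -> AAHC -> back-fitting -> metrics.

The segmentation follows the standard resting-state recipe: topographic maps
at the local maxima of global field power are clustered with the
atomize-agglomerate hierarchical procedure (AAHC) into K=4 polarity-invariant
classes; every sample is then labeled by the best-fitting class map, and the
label sequence yields per-class duration (ms), occurrence (1/s), coverage and
global explained variance (GEV).

Polarity invariance runs through everything: a cluster's centroid is the
dominant principal direction of its member maps (not their plain mean), the
criterion atomized at each step is the cluster contributing least GEV, and
all correlations are compared in absolute value.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .maps import gfp, spatial_correlation, zero_mean
from .preprocess import EpochSet

__all__ = [
    "MicrostateModel",
    "LabelSequence",
    "MicrostateStats",
    "find_gfp_peaks",
    "extract_peak_maps",
    "aahc",
    "cluster_grand_mean",
    "sort_maps",
    "assign_subject_maps",
    "backfit",
    "compute_stats",
    "segment_subject",
    "MicrostateSegmentation",
    "MicrostateSegmentationResults",
]


@dataclass
class MicrostateModel:
    """K labeled microstate maps with their explained-variance shares."""

    maps: np.ndarray  # (K, n_channels), zero-mean, unit norm
    labels: tuple[str, ...]
    gev_per_map: np.ndarray
    gev_total: float
    level: str = "subject"  # or "grand_mean"
    sort_objective: float | None = None
    #: for models fitted by AAHC: cluster index of each input peak map
    assignment: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.gev_per_map = np.asarray(self.gev_per_map, dtype=float)
        self.labels = tuple(self.labels)
        if self.maps.ndim != 2 or self.maps.shape[0] != len(self.labels):
            raise ValueError("maps must be (K, n_channels) matching labels")
        if np.max(np.abs(self.maps.mean(axis=1))) > 1e-8:
            raise ValueError("microstate maps must be zero-mean across channels")
        if not (-1e-9 <= self.gev_total <= 1 + 1e-9):
            raise ValueError("gev_total must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class LabelSequence:
    """Per-sample microstate labels, with the GFP trace and fit quality.

    ``labels``, ``gfp`` and ``fit_corr`` all have shape
    ``(n_epochs, n_times)``; ``fit_corr`` is the polarity-invariant spatial
    correlation of each sample with its assigned map (the GEV ingredient).
    """

    labels: np.ndarray
    gfp: np.ndarray
    fit_corr: np.ndarray
    sfreq: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return self.labels.shape[0]

    @property
    def n_times(self) -> int:
        return self.labels.shape[1]


@dataclass
class MicrostateStats:
    """Per-subject stability metrics over the K microstate classes."""

    duration_ms: dict[str, float]
    occurrence_hz: dict[str, float]
    coverage: dict[str, float]
    mean_duration: float
    mean_occurrence: float
    gev_total: float
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for k in self.duration_ms:
            out[f"duration_{k}_ms"] = self.duration_ms[k]
        for k in self.occurrence_hz:
            out[f"occurrence_{k}_hz"] = self.occurrence_hz[k]
        for k in self.coverage:
            out[f"coverage_{k}"] = self.coverage[k]
        out["mean_duration_ms"] = self.mean_duration
        out["mean_occurrence_hz"] = self.mean_occurrence
        out["gev_total"] = self.gev_total
        return out


# --------------------------------------------------------------------------
# GFP peaks
# --------------------------------------------------------------------------


def find_gfp_peaks(gfp_trace: np.ndarray) -> np.ndarray:
    """Interior local maxima: ``g[i-1] < g[i] >= g[i+1]``.

    Operates on a single epoch's trace; callers handle epochs independently
    so no peak spans an epoch boundary.
    """
    g = np.asarray(gfp_trace, dtype=float)
    if g.size == 0:
        raise ValueError("empty GFP trace")
    if g.size < 3:
        return np.empty(0, dtype=int)
    interior = (g[1:-1] > g[:-2]) & (g[1:-1] >= g[2:])
    return np.flatnonzero(interior) + 1


def extract_peak_maps(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Collect the maps at GFP peaks across all epochs.

    Returns ``(maps, weights)`` where `maps` is ``(n_peaks, n_channels)``
    (zero-mean) and `weights` the GFP value at each peak.
    """
    maps, weights = [], []
    for e in range(epochs.n_epochs):
        data = epochs.epochs[e]
        trace = gfp(data, axis=0)
        peaks = find_gfp_peaks(trace)
        if peaks.size:
            maps.append(zero_mean(data[:, peaks], axis=0).T)
            weights.append(trace[peaks])
    if not maps:
        raise ValueError("no GFP peaks found in any epoch")
    return np.concatenate(maps), np.concatenate(weights)


# --------------------------------------------------------------------------
# AAHC
# --------------------------------------------------------------------------


def _principal_direction(scatter: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = np.linalg.eigh(scatter)
    v = vecs[:, -1]
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:  # deterministic sign
        v = -v
    return float(vals[-1]), v


def aahc(
    peak_maps: np.ndarray,
    K: int,
    weights: np.ndarray | None = None,
    level: str = "subject",
) -> MicrostateModel:
    """Atomize-agglomerate hierarchical clustering of topographic maps.

    Starting from singleton clusters, the cluster contributing least global
    explained variance is repeatedly dissolved ("atomized") and each of its
    member maps is reassigned to the cluster whose centroid it correlates
    with most strongly in absolute value. A cluster's centroid is the first
    principal direction of its (GFP-weighted) member maps, so the procedure
    is blind to map polarity. Stops at `K` clusters.

    `weights` defaults to each map's GFP. Returns maps ordered by
    decreasing explained variance with numeric labels; use
    :func:`sort_maps` to impose the canonical A-D order.
    """
    X = np.asarray(peak_maps, dtype=float)
    if X.ndim != 2:
        raise ValueError("peak_maps must be (n_maps, n_channels)")
    n, C = X.shape
    if n < K:
        raise ValueError(f"need at least K={K} maps, got {n}")
    if K < 1:
        raise ValueError("K must be >= 1")
    if np.max(np.abs(X.mean(axis=1))) > 1e-6 * max(np.abs(X).max(), 1e-30):
        raise ValueError("peak maps must be zero-mean (average reference) across channels")
    if weights is None:
        weights = gfp(X, axis=1)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError("weights must be one scalar per map")
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-variance peak map")
    U = X / norms[:, None]
    wu = U * w[:, None]  # rows scaled by gfp weight
    total = float(np.sum(w**2))
    if total == 0:
        raise ValueError("all peak weights are zero")

    members: list[list[int] | None] = [[i] for i in range(n)]
    scatters = [np.outer(wu[i], wu[i]) for i in range(n)]
    contribs = np.array([w[i] ** 2 for i in range(n)], dtype=float)
    centroids = U.copy()
    active = np.ones(n, dtype=bool)
    n_active = n

    while n_active > K:
        cand = np.where(active, contribs, np.inf)
        worst = int(np.argmin(cand))
        active[worst] = False
        n_active -= 1
        movers = members[worst]
        members[worst] = None
        act_idx = np.flatnonzero(active)
        cent = np.stack([centroids[j] for j in act_idx])
        corr2 = (U[movers] @ cent.T) ** 2
        targets = act_idx[np.argmax(corr2, axis=1)]
        changed = set()
        for m, tgt in zip(movers, targets):
            members[tgt].append(m)
            scatters[tgt] = scatters[tgt] + np.outer(wu[m], wu[m])
            changed.add(int(tgt))
        for j in changed:
            lam, v = _principal_direction(scatters[j])
            contribs[j] = lam
            centroids[j] = v

    act_idx = np.flatnonzero(active)
    order = act_idx[np.argsort(-contribs[act_idx])]
    final_maps = np.stack([centroids[j] for j in order])
    gev_per = contribs[order] / total

    # collapse duplicate centroids produced by rank-deficient input
    keep: list[int] = []
    merged_into: dict[int, int] = {}
    for i in range(len(order)):
        dup_of = next(
            (j for j in keep if abs(final_maps[i] @ final_maps[j]) > 1 - 1e-9), None
        )
        if dup_of is not None:
            merged_into[i] = dup_of
            warnings.warn(
                "degenerate AAHC input: effective number of clusters below K; "
                "returning fewer maps",
                RuntimeWarning,
                stacklevel=2,
            )
        else:
            keep.append(i)
    cluster_of = {int(order[i]): keep.index(merged_into.get(i, i)) for i in range(len(order))}
    assignment = np.empty(n, dtype=int)
    for j in order:
        for m in members[j]:
            assignment[m] = cluster_of[int(j)]
    gev_adj = gev_per.copy()
    for i, j in merged_into.items():
        gev_adj[j] += gev_adj[i]
    final_maps = final_maps[keep]
    gev_per = gev_adj[keep]
    labels = tuple(str(i + 1) for i in range(len(keep)))
    return MicrostateModel(
        maps=final_maps,
        labels=labels,
        gev_per_map=gev_per,
        gev_total=float(gev_per.sum()),
        level=level,
        assignment=assignment,
    )


def cluster_grand_mean(subject_models: list[MicrostateModel], K: int) -> MicrostateModel:
    """Pool all subjects' maps and re-cluster them into K grand-mean maps."""
    if len(subject_models) < 2:
        raise ValueError("grand-mean clustering needs >= 2 subject models")
    C = subject_models[0].n_channels
    if any(m.n_channels != C for m in subject_models):
        raise ValueError("subject models have mismatched channel counts")
    pooled = np.concatenate([m.maps for m in subject_models])
    model = aahc(pooled, K, weights=np.ones(len(pooled)), level="grand_mean")
    return model


# --------------------------------------------------------------------------
# map ordering
# --------------------------------------------------------------------------


def _template_array(templates) -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(templates, MicrostateModel):
        return templates.maps, templates.labels
    return np.asarray(templates, dtype=float), None


def sort_maps(model: MicrostateModel, templates) -> MicrostateModel:
    """Relabel `model` to best match `templates` (exhaustive over K!).

    Maximizes the summed polarity-invariant spatial correlation between
    ``model.maps[perm[k]]`` and ``templates[k]``; ties resolve to the
    lexicographically smallest permutation. The optimal objective is stored
    on the result as ``sort_objective``.
    """
    tmpl, tmpl_labels = _template_array(templates)
    K = model.n_states
    if tmpl.shape[0] < K or tmpl.shape[1] != model.n_channels:
        raise ValueError("templates must provide K maps with matching channels")
    corr = np.abs(
        np.array(
            [
                [spatial_correlation(model.maps[i], tmpl[k]) for k in range(K)]
                for i in range(K)
            ]
        )
    )
    best_perm, best_obj = None, -np.inf
    for perm in itertools.permutations(range(K)):
        obj = sum(corr[perm[k], k] for k in range(K))
        if obj > best_obj + 1e-12:
            best_obj, best_perm = obj, perm
    labels = tmpl_labels[:K] if tmpl_labels else tuple("ABCDEFGH"[:K])
    assignment = None
    if model.assignment is not None:
        inverse = np.empty(K, dtype=int)
        inverse[list(best_perm)] = np.arange(K)
        assignment = inverse[model.assignment]
    return MicrostateModel(
        maps=model.maps[list(best_perm)],
        labels=labels,
        gev_per_map=model.gev_per_map[list(best_perm)],
        gev_total=model.gev_total,
        level=model.level,
        sort_objective=float(best_obj),
        assignment=assignment,
    )


def assign_subject_maps(
    subject_model: MicrostateModel, grand_mean_model: MicrostateModel
) -> MicrostateModel:
    """Assign a subject's maps to the grand-mean classes (same optimal search)."""
    if subject_model.n_states != grand_mean_model.n_states:
        raise ValueError("subject and grand-mean models must share K")
    return sort_maps(subject_model, grand_mean_model)


# --------------------------------------------------------------------------
# back-fitting and metrics
# --------------------------------------------------------------------------


def backfit(epochs: EpochSet, model: MicrostateModel) -> LabelSequence:
    """Label every sample of every epoch with its best-fitting class.

    GFP peaks get the map with the highest polarity-invariant correlation;
    every other sample inherits the label of its nearest peak within the
    epoch (midpoint rule, ties to the earlier peak). An epoch without any
    peak falls back to per-sample best fit and is flagged in provenance.
    No temporal smoothing is applied.
    """
    if model.n_channels != epochs.epochs.shape[1]:
        raise ValueError("model and epochs must share channel count")
    n_ep, _C, L = epochs.epochs.shape
    labels = np.empty((n_ep, L), dtype=int)
    gfps = np.empty((n_ep, L))
    corrs = np.empty((n_ep, L))
    peakless: list[int] = []
    M = model.maps  # (K, C), unit norm, zero mean
    for e in range(n_ep):
        data = zero_mean(epochs.epochs[e], axis=0)
        trace = gfp(data, axis=0)
        gfps[e] = trace
        norms = np.linalg.norm(data, axis=0)
        safe = np.where(norms > 0, norms, 1.0)
        unit = data / safe[None, :]
        corr_all = np.abs(M @ unit)  # (K, L)
        peaks = find_gfp_peaks(trace)
        if peaks.size == 0:
            peakless.append(e)
            lab = np.argmax(corr_all, axis=0)
        else:
            peak_labels = np.argmax(corr_all[:, peaks], axis=0)
            if peaks.size == 1:
                lab = np.full(L, peak_labels[0])
            else:
                mids = (peaks[:-1] + peaks[1:]) / 2.0
                which = np.searchsorted(mids, np.arange(L), side="left")
                lab = peak_labels[which]
        labels[e] = lab
        corrs[e] = np.where(norms > 0, corr_all[lab, np.arange(L)], 0.0)
    return LabelSequence(
        labels=labels,
        gfp=gfps,
        fit_corr=corrs,
        sfreq=epochs.sfreq,
        provenance={"peakless_epochs": peakless, "state_labels": model.labels},
    )


def _epoch_runs(lab: np.ndarray) -> list[tuple[int, int, int]]:
    """(label, start, stop) for maximal constant runs; stop exclusive."""
    change = np.flatnonzero(np.diff(lab) != 0)
    starts = np.concatenate([[0], change + 1])
    stops = np.concatenate([change + 1, [lab.size]])
    return [(int(lab[s]), int(s), int(t)) for s, t in zip(starts, stops)]


def compute_stats(
    seq: LabelSequence,
    model: MicrostateModel,
    exclude_truncated: bool = True,
) -> MicrostateStats:
    """Duration, occurrence, coverage and GEV from a label sequence.

    A run is a maximal same-label span within one epoch (epochs are
    discontinuous, so runs never merge across them). With
    ``exclude_truncated=True`` (default), runs touching an epoch edge are
    excluded from duration averages (falling back to all runs, flagged, if a
    class has only truncated runs) and occurrences count runs starting
    strictly inside the epoch. With ``exclude_truncated=False`` every run
    enters both, which makes the accounting identity
    ``sum_k duration_k * occurrence_k = 1000 * sum_k coverage_k`` exact.
    """
    if seq.labels.size == 0:
        raise ValueError("empty label sequence")
    K = model.n_states
    L = seq.n_times
    flags: list[str] = []
    dur_all: dict[int, list[int]] = {k: [] for k in range(K)}
    dur_interior: dict[int, list[int]] = {k: [] for k in range(K)}
    occ_count = np.zeros(K)
    sample_count = np.zeros(K)
    for e in range(seq.n_epochs):
        for k, s, t in _epoch_runs(seq.labels[e]):
            dur_all[k].append(t - s)
            if s > 0 and t < L:
                dur_interior[k].append(t - s)
            if (s > 0) if exclude_truncated else True:
                occ_count[k] += 1
        counts = np.bincount(seq.labels[e], minlength=K)
        sample_count += counts
    total_samples = seq.labels.size
    total_seconds = total_samples / seq.sfreq
    ms_per_sample = 1000.0 / seq.sfreq

    duration: dict[str, float] = {}
    occurrence: dict[str, float] = {}
    coverage: dict[str, float] = {}
    for k, name in enumerate(model.labels):
        if not dur_all[k]:
            duration[name] = float("nan")
            flags.append(f"state {name} never occurs")
        else:
            runs = dur_interior[k] if exclude_truncated else dur_all[k]
            if exclude_truncated and not runs:
                runs = dur_all[k]
                flags.append(f"state {name}: only edge-truncated runs")
            duration[name] = float(np.mean(runs)) * ms_per_sample
        occurrence[name] = float(occ_count[k] / total_seconds)
        coverage[name] = float(sample_count[k] / total_samples)

    durs = np.array([duration[n] for n in model.labels])
    mean_duration = float(np.nanmean(durs))
    mean_occurrence = float(np.mean([occurrence[n] for n in model.labels]))
    gev_total = float(
        np.sum((seq.gfp * seq.fit_corr) ** 2) / np.sum(seq.gfp**2)
    )
    return MicrostateStats(
        duration_ms=duration,
        occurrence_hz=occurrence,
        coverage=coverage,
        mean_duration=mean_duration,
        mean_occurrence=mean_occurrence,
        gev_total=gev_total,
        flags=flags,
    )


def segment_subject(
    epochs: EpochSet,
    grand_mean_model: MicrostateModel | None = None,
    K: int = 4,
    templates: np.ndarray | MicrostateModel | None = None,
    exclude_truncated: bool = True,
) -> tuple[MicrostateModel, LabelSequence, MicrostateStats]:
    """Full single-subject chain: peaks -> AAHC -> (assign) -> backfit -> stats.

    If a grand-mean model is given the subject's maps are assigned to its
    classes and the *grand-mean* labels are used; otherwise `templates`
    (e.g. the canonical A-D prototypes) impose the ordering, and with
    neither the maps stay in explained-variance order.
    """
    peak_maps, weights = extract_peak_maps(epochs)
    model = aahc(peak_maps, K, weights=weights)
    if grand_mean_model is not None:
        model = assign_subject_maps(model, grand_mean_model)
    elif templates is not None:
        model = sort_maps(model, templates)
    seq = backfit(epochs, model)
    stats = compute_stats(seq, model, exclude_truncated=exclude_truncated)
    return model, seq, stats


# --------------------------------------------------------------------------
# model-object interface
# --------------------------------------------------------------------------


class MicrostateSegmentation:
    """Microstate model of one subject's epoched EEG.

    Parameters
    ----------
    epochs
        Average-referenced :class:`~microtrait.preprocess.EpochSet`.
    n_states
        Number of microstate classes (K); 4 by standard convention.
    templates
        Optional template maps (array or model) used to impose the A-D
        ordering; a grand-mean model may be passed instead via `grand_mean`.
    exclude_truncated
        Duration policy for edge-truncated runs (see :func:`compute_stats`).
    """

    def __init__(
        self,
        epochs: EpochSet,
        n_states: int = 4,
        templates=None,
        grand_mean: MicrostateModel | None = None,
        exclude_truncated: bool = True,
    ):
        if epochs.reference != "average":
            raise ValueError("epochs must be average-referenced before segmentation")
        self.epochs = epochs
        self.n_states = n_states
        self.templates = templates
        self.grand_mean = grand_mean
        self.exclude_truncated = exclude_truncated

    def fit(self) -> "MicrostateSegmentationResults":
        model, seq, stats = segment_subject(
            self.epochs,
            grand_mean_model=self.grand_mean,
            K=self.n_states,
            templates=self.templates,
            exclude_truncated=self.exclude_truncated,
        )
        return MicrostateSegmentationResults(self, model, seq, stats)


@dataclass
class MicrostateSegmentationResults:
    """Fitted microstate model, label sequence and stability metrics."""

    segmentation: MicrostateSegmentation
    model: MicrostateModel
    sequence: LabelSequence
    stats: MicrostateStats

    def summary(self) -> str:
        s = self.stats
        lines = [
            "Microstate segmentation",
            f"  states: {', '.join(self.model.labels)}   "
            f"epochs: {self.sequence.n_epochs}   GEV: {s.gev_total:.3f}",
            f"  {'state':>5} {'duration_ms':>12} {'occurrence_hz':>14} {'coverage':>9} {'gev':>7}",
        ]
        for i, name in enumerate(self.model.labels):
            lines.append(
                f"  {name:>5} {s.duration_ms[name]:>12.1f} "
                f"{s.occurrence_hz[name]:>14.2f} {s.coverage[name]:>9.3f} "
                f"{self.model.gev_per_map[i]:>7.3f}"
            )
        lines.append(
            f"  mean duration {s.mean_duration:.1f} ms, "
            f"mean occurrence {s.mean_occurrence:.2f}/s"
        )
        return "\n".join(lines)

    def plot_maps(self, montage, axes=None):
        """Quick scalp scatter of the class maps (top view)."""
        import matplotlib.pyplot as plt

        K = self.model.n_states
        if axes is None:
            _fig, axes = plt.subplots(1, K, figsize=(3 * K, 3))
        pos = montage.positions
        for ax, name, m in zip(np.atleast_1d(axes), self.model.labels, self.model.maps):
            lim = np.abs(m).max()
            ax.scatter(pos[:, 0], pos[:, 1], c=m, cmap="RdBu_r", vmin=-lim, vmax=lim, s=60)
            ax.set_title(f"Microstate {name}")
            ax.set_aspect("equal")
            ax.axis("off")
        return axes
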