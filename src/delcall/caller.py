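"""End-to-end deletion calling and evaluation.

The reference is partitioned into consecutive non-overlapping 50 bp windows;
each window is rendered to a pileup image and scored by the CNN; maximal runs
of deletion-scored windows (tolerating one gap window) become candidates; each
candidate is then curated — clustered, screened for false positives and
breakpoint-refined — before being emitted as a call.

Evaluation matches calls to truth deletions one-to-one greedily under 50%
reciprocal overlap and reports precision, sensitivity, F-score and per-side
breakpoint distances.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import cnn
from .curation import DistanceParams, curate_candidate
from .encode import WINDOW_BP, label_window, render_batch
from .features import InsertStats, ReadIndex, estimate_insert_stats, position_features
from .records import AlignedRead
from .simulate import DeletionSpec, Scene


@dataclass(frozen=True)
class DeletionCall:
    chrom: str
    start: int                 # 0-based half-open, refined
    end: int
    probability: float         # mean classifier probability over support windows
    n_support_windows: int
    verdict: str = "true_deletion"
    imprecise: bool = False

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("call end must exceed start")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    breakpoint_distances: list[int] = field(default_factory=list)

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def sensitivity(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def f_score(self) -> float | None:
        p, s = self.precision, self.sensitivity
        if p is None or s is None or (p + s) == 0:
            return None
        return 2 * p * s / (p + s)


@dataclass
class CallerParams:
    prob_threshold: float = 0.5
    max_gap_windows: int = 2
    min_call_length: int = WINDOW_BP
    flank: int = 800           # context added around a candidate for curation
    gamma: float = 4.0
    tau: float = 0.6
    distance: DistanceParams = field(default_factory=DistanceParams)
    min_evidence: int = 3      # split/discordant support required of a candidate
    seed: int = 0
    curate: bool = True


# ---------------------------------------------------------------------------
# window classification
# ---------------------------------------------------------------------------

def window_grid(ref_length: int) -> np.ndarray:
    """Start positions of the consecutive non-overlapping 50 bp windows."""
    return np.arange(0, ref_length - WINDOW_BP + 1, WINDOW_BP, dtype=np.int64)


def render_windows(index: ReadIndex, chrom: str, starts: Sequence[int],
                   stats: InsertStats, chunk: int = 256) -> np.ndarray:
    """Render a batch of windows to a (n, 256, 256, 3) uint8 stack.

    Windows are rendered in chunks; the read query is padded by the longest
    pair outer span so column discordant counts include pairs whose reads lie
    outside the window.
    """
    starts = np.asarray(starts, dtype=np.int64)
    images = np.empty((len(starts), 256, 256, 3), dtype=np.uint8)
    pad = index.max_outer_span
    for i in range(0, len(starts), chunk):
        sub = starts[i:i + chunk]
        reads = index.overlapping(int(sub[0]) - pad, int(sub[-1]) + WINDOW_BP)
        images[i:i + len(sub)] = render_batch(reads, chrom, sub, stats)
    return images


def classify_windows(model: cnn.Model, index: ReadIndex, chrom: str,
                     ref_length: int, stats: InsertStats,
                     batch: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Deletion probability for every 50 bp window of the reference."""
    starts = window_grid(ref_length)
    probs = np.empty(len(starts), dtype=np.float64)
    for i in range(0, len(starts), batch):
        imgs = render_windows(index, chrom, starts[i:i + batch], stats)
        probs[i:i + batch] = cnn.predict(model, imgs)
    return starts, probs


def merge_windows(starts: np.ndarray, probs: np.ndarray,
                  threshold: float = 0.5, max_gap: int = 1,
                  min_length: int = WINDOW_BP) -> list[tuple[int, int]]:
    """Merge deletion-scored windows into candidate intervals.

    Runs of windows with probability >= threshold are joined across at most
    ``max_gap`` sub-threshold windows; candidates shorter than ``min_length``
    are dropped.
    """
    hits = np.flatnonzero(probs >= threshold)
    if hits.size == 0:
        return []
    candidates = []
    run_start = prev = hits[0]
    for h in hits[1:]:
        if h - prev <= max_gap + 1:
            prev = h
        else:
            candidates.append((int(starts[run_start]), int(starts[prev]) + WINDOW_BP))
            run_start = prev = h
    candidates.append((int(starts[run_start]), int(starts[prev]) + WINDOW_BP))
    return [(s, e) for s, e in candidates if e - s >= min_length]


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_deletions(model: cnn.Model, reads: Sequence[AlignedRead], chrom: str,
                   ref_length: int, stats: InsertStats | None = None,
                   params: CallerParams | None = None) -> list[DeletionCall]:
    """Scan, classify, merge, curate and refine deletion calls on one chromosome."""
    if model is None:
        raise ValueError("a trained model is required")
    params = params or CallerParams()
    if not reads:
        return []
    if stats is None:
        stats = estimate_insert_stats(reads)
    index = ReadIndex(reads)
    starts, probs = classify_windows(model, index, chrom, ref_length, stats)
    candidates = merge_windows(starts, probs, threshold=params.prob_threshold,
                               max_gap=params.max_gap_windows,
                               min_length=params.min_call_length)
    calls: list[DeletionCall] = []
    for c0, c1 in candidates:
        in_cand = (starts >= c0) & (starts < c1)
        mean_prob = float(probs[in_cand].mean()) if in_cand.any() else 0.0
        n_support = int((probs[in_cand] >= params.prob_threshold).sum())
        if not params.curate:
            calls.append(DeletionCall(chrom, c0, c1, mean_prob, n_support,
                                      imprecise=True))
            continue
        r0 = max(0, c0 - params.flank)
        r1 = min(ref_length, c1 + params.flank)
        track = position_features(index.overlapping(r0, r1), chrom, r0, r1,
                                  stats=stats, check_sorted=False)
        # any true deletion is bracketed by encompassing pairs and junction
        # reads; a candidate without either signature is a depth artifact
        if max(track.discordant.max(), track.split.max()) < params.min_evidence:
            continue
        outcome = curate_candidate(track, (c0, c1), gamma=params.gamma,
                                   tau=params.tau, params=params.distance,
                                   seed=params.seed)
        if outcome.verdict != "true_deletion":
            continue
        s, e = outcome.estimate.interval
        imprecise = False
        if e - s < WINDOW_BP:      # refinement collapsed: fall back to candidate
            s, e, imprecise = c0, c1, True
        calls.append(DeletionCall(chrom, s, e, mean_prob, n_support,
                                  imprecise=imprecise))
    return _merge_overlapping_calls(calls)


def _merge_overlapping_calls(calls: list[DeletionCall]) -> list[DeletionCall]:
    """Union refined calls that overlap (one deletion, several candidates)."""
    merged: list[DeletionCall] = []
    for c in sorted(calls, key=lambda c: (c.chrom, c.start, c.end)):
        if merged and c.chrom == merged[-1].chrom and c.start < merged[-1].end:
            prev = merged.pop()
            merged.append(DeletionCall(
                chrom=prev.chrom, start=prev.start, end=max(prev.end, c.end),
                probability=max(prev.probability, c.probability),
                n_support_windows=prev.n_support_windows + c.n_support_windows,
                imprecise=prev.imprecise or c.imprecise))
        else:
            merged.append(c)
    return merged


def calls_to_vcf(path: str, calls: Sequence[DeletionCall]) -> None:
    """Write calls as VCF 4.2 DEL records (PROB and SUPPORT in INFO)."""
    from .records import VCF_HEADER
    contigs = sorted({c.chrom for c in calls}) or ["chr1"]
    header = VCF_HEADER.replace(
        "##contig=<ID=CONTIGS>\n",
        "".join(f"##contig=<ID={ch}>\n" for ch in contigs))
    header = header.replace(
        "##FORMAT", '##INFO=<ID=PROB,Number=1,Type=Float,Description='
        '"Mean classifier probability">\n'
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description='
        '"Supporting 50 bp windows">\n##FORMAT')
    with open(path, "w") as fh:
        fh.write(header.replace("SAMPLE", "calls"))
        for c in calls:
            info = (f"SVTYPE=DEL;END={c.end};SVLEN={-(c.end - c.start)};"
                    f"PROB={c.probability:.4f};SUPPORT={c.n_support_windows}")
            if c.imprecise:
                info += ";IMPRECISE"
            fh.write(f"{c.chrom}\t{c.start}\t.\tN\t<DEL>\t.\tPASS\t{info}"
                     f"\tGT\t./.\n")


def calls_from_vcf(path: str) -> list[DeletionCall]:
    import pysam
    calls = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            calls.append(DeletionCall(
                chrom=rec.chrom, start=rec.pos, end=int(rec.stop),
                probability=round(float(rec.info["PROB"]), 4),
                n_support_windows=int(rec.info["SUPPORT"]),
                imprecise="IMPRECISE" in rec.info))
    return calls


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if inter == 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def evaluate(calls: Sequence[DeletionCall], truth: Sequence[DeletionSpec],
             min_reciprocal_overlap: float = 0.5) -> EvalReport:
    """Greedy one-to-one matching of calls to truth by reciprocal overlap."""
    pairs = []
    for i, c in enumerate(calls):
        for j, t in enumerate(truth):
            if c.chrom != t.chrom:
                continue
            ro = _reciprocal_overlap((c.start, c.end), (t.start, t.end))
            if ro >= min_reciprocal_overlap:
                pairs.append((ro, i, j))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_c: set[int] = set()
    used_t: set[int] = set()
    distances: list[int] = []
    for ro, i, j in pairs:
        if i in used_c or j in used_t:
            continue
        used_c.add(i)
        used_t.add(j)
        distances.append(abs(calls[i].start - truth[j].start))
        distances.append(abs(calls[i].end - truth[j].end))
    tp = len(used_t)
    return EvalReport(tp=tp, fp=len(calls) - tp, fn=len(truth) - tp,
                      breakpoint_distances=distances)


# ---------------------------------------------------------------------------
# training-set assembly and the desk-scale pipeline
# ---------------------------------------------------------------------------

def make_training_set(scene: Scene, stats: InsertStats | None = None,
                      neg_ratio: float = 2.0, seed: int = 0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Window images + 0/1 labels from a scene with known deletions.

    All deletion-labeled windows are kept; wild-type windows are downsampled
    to at most ``neg_ratio`` times the deletion count (genome windows are
    overwhelmingly label 0).
    """
    if stats is None:
        stats = estimate_insert_stats(scene.reads)
    index = ReadIndex(scene.reads)
    starts = window_grid(scene.length)
    truth = [(d.start, d.end) for d in scene.deletions]
    labels = np.array([label_window(int(s), int(s) + WINDOW_BP, truth)
                       for s in starts])
    pos = starts[labels == 1]
    neg = starts[labels == 0]
    rng = np.random.default_rng(seed)
    n_neg = min(len(neg), int(round(neg_ratio * max(len(pos), 1))))
    neg = rng.choice(neg, size=n_neg, replace=False) if n_neg else neg[:0]
    chosen = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(len(pos), dtype=np.int64),
                        np.zeros(len(neg), dtype=np.int64)])
    order = np.argsort(chosen, kind="stable")   # renderer wants sorted windows
    chosen, y = chosen[order], y[order]
    images = render_windows(index, scene.chrom, chosen, stats)
    return images, y


def train_on_scene(scene: Scene, preset: str = "small", epochs: int = 12,
                   seed: int = 0, batch_size: int = 128,
                   validation_fraction: float = 0.0
                   ) -> tuple[cnn.Model, cnn.TrainHistory]:
    """Build and train a window classifier from a labeled scene."""
    images, labels = make_training_set(scene, seed=seed)
    model = cnn.build_model(preset, seed=seed)
    cfg = cnn.TrainConfig(batch_size=batch_size, epochs=epochs, seed=seed,
                          preset=preset, validation_fraction=validation_fraction)
    history = cnn.train(model, images, labels, cfg)
    return model, history


# ---------------------------------------------------------------------------
# coverage titration
# ---------------------------------------------------------------------------

def downsample_reads(reads: Sequence[AlignedRead], fraction: float,
                     seed: int = 0) -> list[AlignedRead]:
    """Keep each fragment (both mates and their supplementaries) with the
    given probability, deterministically from the fragment name and seed."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(reads)
    kept = []
    threshold = int(fraction * 2**32)
    for r in reads:
        h = zlib.crc32(f"{r.name}:{seed}".encode())
        if h < threshold:
            kept.append(r)
    return kept


def realized_depth(reads: Sequence[AlignedRead], ref_length: int) -> float:
    """Genome-wide mean depth of primary aligned bases."""
    total = sum(b1 - b0 for r in reads if r.is_primary and not r.is_duplicate
                for b0, b1 in r.aligned_blocks())
    return total / ref_length


def coverage_titration(train_scene: Scene, test_scene: Scene,
                       coverages: Sequence[float], seed: int = 0,
                       epochs: int = 10, params: CallerParams | None = None):
    """Down-sample both scenes to each coverage, retrain and re-evaluate.

    Returns a pandas DataFrame with one row per coverage (precision,
    sensitivity, F-score, realized depth).  Requires every target coverage to
    be at most the scenes' source coverage.
    """
    import pandas as pd

    source = min(train_scene.lib.coverage, test_scene.lib.coverage)
    for c in coverages:
        if c <= 0:
            raise ValueError("coverages must be positive")
        if c > source:
            raise ValueError(f"target coverage {c}x exceeds source {source}x")
    rows = []
    for c in coverages:
        frac = c / train_scene.lib.coverage
        tr_reads = downsample_reads(train_scene.reads, frac, seed=seed)
        te_reads = downsample_reads(test_scene.reads,
                                    c / test_scene.lib.coverage, seed=seed + 1)
        tr_scene = Scene(train_scene.chrom, train_scene.reference,
                         train_scene.deletions, train_scene.lib, tr_reads)
        model, _ = train_on_scene(tr_scene, epochs=epochs, seed=seed)
        calls = call_deletions(model, te_reads, test_scene.chrom,
                               test_scene.length, params=params)
        report = evaluate(calls, test_scene.deletions)
        rows.append({
            "coverage": c,
            "realized_depth": realized_depth(te_reads, test_scene.length),
            "tp": report.tp, "fp": report.fp, "fn": report.fn,
            "precision": report.precision, "sensitivity": report.sensitivity,
            "f_score": report.f_score,
        })
    return pd.DataFrame(rows)
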