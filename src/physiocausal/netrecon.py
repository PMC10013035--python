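"""Causal-network reconstruction from sleep-stage patches.

For every stationary patch the conditional G-value is computed for all six
ordered channel pairs among H (heart rate), B (breathing rate) and E (EEG
alpha amplitude), conditioning on the remaining channel.  Per edge, stage
and resolution, patch G-values are averaged weighted by patch length, and a
bootstrap over patches (resampling with replacement, unweighted means)
yields the standard error.  Surrogate networks — channels recombined across
different subjects so no genuine coupling can exist — provide the baseline
against which real edges are judged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field

import numpy as np

from .granger import g_conditional
from .physio import Hypnogram, StagePatch, coarse_grain, partition_by_stage
from .signals import CHANNELS, Signal
from .stationarity import DEFAULT_ORDERS, split_patches

__all__ = [
    "PatchG",
    "NetworkEdge",
    "SubjectRecording",
    "patch_g_all_pairs",
    "weighted_mean_g",
    "bootstrap_se",
    "build_network",
    "cohort_network",
    "surrogate_cohort",
    "surrogate_network",
    "write_network",
    "read_network",
    "EDGES",
]

logger = logging.getLogger(__name__)

EDGES = tuple(
    (s, t) for s in CHANNELS for t in CHANNELS if s != t
)  # six directed pairs


@dataclass(frozen=True)
class PatchG:
    subject: str
    stage: str
    resolution: float
    source: str
    target: str
    g_value: float
    length: int  # patch length in samples
    order: int


@dataclass(frozen=True)
class NetworkEdge:
    source: str
    target: str
    stage: str
    resolution: float
    mean_g: float
    se: float
    n_patches: int


@dataclass(frozen=True)
class SubjectRecording:
    """One subject's three 1 Hz channels plus the hypnogram."""

    subject: str
    H: Signal
    B: Signal
    E: Signal
    hypnogram: Hypnogram

    @property
    def channels(self) -> dict[str, Signal]:
        return {"H": self.H, "B": self.B, "E": self.E}


def patch_g_all_pairs(
    channels, order: int, subject: str = "", stage: str = "", resolution: float = 1.0
) -> list[PatchG]:
    """Conditional G for all six ordered pairs of a standardized patch triple.

    For pair (s -> t) the third channel is the conditioning signal.  Patches
    shorter than ``2*order + 2`` samples yield no records (logged).
    """
    by_label = {getattr(c, "label", None) or lab: c for lab, c in zip(CHANNELS, channels)}
    if set(by_label) != set(CHANNELS):
        by_label = dict(zip(CHANNELS, channels))
    n = len(next(iter(by_label.values())))
    if n < 2 * order + 2:
        logger.warning("patch of %d samples too short for order %d; skipped", n, order)
        return []
    records = []
    for src, tgt in EDGES:
        other = next(c for c in CHANNELS if c not in (src, tgt))
        res = g_conditional(by_label[tgt], by_label[src], [by_label[other]], p=order)
        records.append(
            PatchG(subject, stage, resolution, src, tgt, res.g_value, n, order)
        )
    return records


def weighted_mean_g(records) -> float:
    """Patch-length-weighted mean G over records of one edge/stage/resolution."""
    records = list(records)
    if not records:
        raise ValueError("no records to average")
    weights = np.array([r.length for r in records], dtype=float)
    values = np.array([r.g_value for r in records], dtype=float)
    return float(np.sum(weights * values) / np.sum(weights))


def bootstrap_se(records, n_boot: int = 100, seed=None, weighted: bool = False) -> float:
    """Bootstrap standard error of the mean patch G.

    Records are resampled with replacement to the original count; per
    resample the unweighted mean is taken (set ``weighted=True`` to weight
    by patch length instead); the SE is the standard deviation of the
    ``n_boot`` resample means.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to bootstrap")
    values = np.array([r.g_value for r in records], dtype=float)
    weights = np.array([r.length for r in records], dtype=float)
    if np.ptp(values) == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    k = values.size
    idx = rng.integers(0, k, size=(n_boot, k))
    if weighted:
        w = weights[idx]
        means = np.sum(w * values[idx], axis=1) / np.sum(w, axis=1)
    else:
        means = values[idx].mean(axis=1)
    return float(means.std(ddof=1))


def build_network(
    records, n_boot: int = 100, seed=None, weighted_bootstrap: bool = False
) -> list[NetworkEdge]:
    """Aggregate patch records into edges per (pair, stage, resolution).

    Combinations with no surviving patch are absent from the result rather
    than reported as zero.
    """
    groups: dict[tuple, list[PatchG]] = {}
    for r in records:
        groups.setdefault((r.source, r.target, r.stage, r.resolution), []).append(r)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    edges = []
    for (src, tgt, stage, resol), seeds in zip(
        sorted(groups), ss.spawn(len(groups))
    ):
        recs = groups[(src, tgt, stage, resol)]
        edges.append(
            NetworkEdge(
                src,
                tgt,
                stage,
                resol,
                weighted_mean_g(recs),
                bootstrap_se(recs, n_boot=n_boot, seed=seeds, weighted=weighted_bootstrap),
                len(recs),
            )
        )
    return edges


def subject_patch_records(
    rec: SubjectRecording,
    resolutions=(1,),
    orders=DEFAULT_ORDERS,
    alpha: float = 0.05,
) -> list[PatchG]:
    """Full per-subject pipeline: coarse-grain, partition, split, fit.

    For each resolution the 1 Hz triple is block-averaged, cut into
    same-stage patches (standardized, wake excluded), each patch split into
    stationary sub-patches by the ADF procedure, and the conditional G of
    all six pairs computed per accepted sub-patch with the accepted order.
    """
    records: list[PatchG] = []
    for factor in resolutions:
        triple = [coarse_grain(rec.channels[c], int(factor)) for c in CHANNELS]
        for patch in partition_by_stage(triple, rec.hypnogram, resolution=float(factor)):
            for sp in split_patches(
                patch.channels, resolution=float(factor), orders=orders, alpha=alpha
            ):
                sub = [c.values[sp.start : sp.end] for c in patch.channels]
                sub = [Signal(v, dt=float(factor), label=c) for v, c in zip(sub, CHANNELS)]
                records.extend(
                    patch_g_all_pairs(
                        sub, sp.order, rec.subject, patch.stage, float(factor)
                    )
                )
    return records


def cohort_network(
    cohort,
    resolutions=(1,),
    orders=DEFAULT_ORDERS,
    alpha: float = 0.05,
    n_boot: int = 100,
    seed=None,
) -> list[NetworkEdge]:
    """Pooled network over a cohort: all subjects' patch records per cell."""
    records: list[PatchG] = []
    for rec in cohort:
        records.extend(subject_patch_records(rec, resolutions, orders, alpha))
    return build_network(records, n_boot=n_boot, seed=seed)


def surrogate_cohort(cohort, shift: int = 1) -> list[SubjectRecording]:
    """Recombine channels across subjects so no genuine coupling survives.

    Pseudo-subject i keeps its own H channel (and hypnogram), takes B from
    subject i+shift and E from subject i+2*shift (cyclically) — a
    derangement over at least three subjects, so the three channels of every
    pseudo-subject come from three different people.  Channels are truncated
    to the shortest donor.
    """
    cohort = list(cohort)
    k = len(cohort)
    if k < 3:
        raise ValueError("surrogate recombination needs at least three subjects")
    if shift % k == 0 or (2 * shift) % k == 0 or shift % k == (2 * shift) % k:
        raise ValueError("shift must place H, B, E donors at three distinct subjects")
    out = []
    for i, rec in enumerate(cohort):
        donor_b = cohort[(i + shift) % k]
        donor_e = cohort[(i + 2 * shift) % k]
        n = min(rec.H.n, donor_b.B.n, donor_e.E.n, rec.hypnogram.duration)
        out.append(
            SubjectRecording(
                subject=f"surr-{rec.subject}",
                H=Signal(rec.H.values[:n], 1.0, "H"),
                B=Signal(donor_b.B.values[:n], 1.0, "B"),
                E=Signal(donor_e.E.values[:n], 1.0, "E"),
                hypnogram=rec.hypnogram,
            )
        )
    return out


def surrogate_network(cohort, shift: int = 1, **kwargs) -> list[NetworkEdge]:
    """Network of the surrogate-recombined cohort (baseline, no true links)."""
    return cohort_network(surrogate_cohort(cohort, shift=shift), **kwargs)


def write_network(edges, path) -> None:
    """Serialize edges as JSON; round-trips losslessly via read_network."""
    doc = {"edges": [asdict(e) for e in edges]}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def read_network(path) -> list[NetworkEdge]:
    with open(path) as fh:
        doc = json.load(fh)
    return [NetworkEdge(**e) for e in doc["edges"]]
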