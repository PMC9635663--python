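"""Two-stage parameter training: sweep clustering grids and pick defaults.

Stage 1 sweeps sequence–sequence clustering parameters; any parameter set
producing even one pham with a false positive is excluded, and among the
survivors the set with the fewest false negatives wins.  Stage 2 sweeps
profile–sequence parameters starting from the fixed stage-1 phams; sets are
retained while their overall false-positive rate stays below a 0.5% cap,
and again the fewest false negatives wins.

Ties are broken by fewer phams, then by grid order.  Runtime is recorded
per parameter set for analysis but never used for selection.
"""

from __future__ import annotations

import csv
import itertools
import time
from dataclasses import dataclass, field
from pathlib import Path

from .alignment import AlignmentCache
from .clustering import (
    ClusterParams,
    Pham,
    cascade_cluster,
    profile_merge,
    select_representative_seq,
)
from .genome_io import NonRedundantSet, expand_clusters
from .qc import DEFAULT_QC_THRESHOLDS, QCThresholds, audit

#: Stage-1 grid: cluster mode, cascade steps, sensitivity, identity,
#: coverage, E-value (in grid order).
SEQUENCE_GRID: dict[str, list] = {
    "cluster_mode": [0, 1, 2],
    "cluster_steps": [1, 2, 3],
    "sensitivity": [1, 4, 7],
    "min_seq_id": [0.5, 0.45, 0.4, 0.35, 0.3],
    "coverage": [0.9, 0.85, 0.8, 0.75, 0.7],
    "evalue": [1e-10, 1e-5, 1e-3],
}

#: Stage-2 grid: cluster mode, profile iterations, sensitivity, identity,
#: coverage, E-value.
PROFILE_GRID: dict[str, list] = {
    "cluster_mode": [0, 1, 2],
    "num_iterations": [1, 2, 3],
    "sensitivity": [1, 4, 7],
    "min_seq_id": [0.35, 0.3, 0.25, 0.2, 0.15],
    "coverage": [0.85, 0.8, 0.75, 0.7, 0.65, 0.6, 0.55],
    "evalue": [1e-5, 1e-3],
}

#: Stage-2 retention cap on the overall false-positive rate.
DEFAULT_FP_CAP = 0.005


@dataclass
class GridSpec:
    """Value lists per parameter for one training stage."""

    stage: str  # "sequence" or "profile"
    values: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in ("sequence", "profile"):
            raise ValueError("stage must be 'sequence' or 'profile'")
        if not self.values:
            self.values = dict(
                SEQUENCE_GRID if self.stage == "sequence" else PROFILE_GRID
            )
        for name, vals in self.values.items():
            if not vals:
                raise ValueError(f"empty value list for {name!r}")

    @property
    def cardinality(self) -> int:
        n = 1
        for vals in self.values.values():
            n *= len(vals)
        return n

    @classmethod
    def from_file(cls, path: str | Path, stage: str) -> "GridSpec":
        """Read a key-value grid file: ``param = v1, v2, ...`` per line.

        Unlisted parameters keep their full default value lists.
        """
        values = dict(SEQUENCE_GRID if stage == "sequence" else PROFILE_GRID)
        int_params = {"cluster_mode", "cluster_steps", "num_iterations",
                      "sensitivity"}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, raw = line.partition("=")
                key = key.strip().replace("-", "_")
                if key not in values:
                    raise ValueError(f"unknown grid parameter {key!r}")
                cast = int if key in int_params else float
                values[key] = [cast(v) for v in raw.replace(",", " ").split()]
        return cls(stage=stage, values=values)


@dataclass
class GridResult:
    """Audit outcome of one parameter set."""

    params: ClusterParams
    n_phams: int
    n_false_negatives: int
    n_false_positives: int
    fp_rate: float
    runtime_seconds: float


def enumerate_grid(spec: GridSpec) -> list[ClusterParams]:
    """Full Cartesian product of the grid, in deterministic grid order."""
    steps_key = "cluster_steps" if spec.stage == "sequence" else "num_iterations"
    names = list(spec.values)
    out = []
    for combo in itertools.product(*(spec.values[n] for n in names)):
        kwargs = dict(zip(names, combo))
        kwargs.setdefault(steps_key, 1)
        out.append(ClusterParams(**kwargs))
    return out


def _phams_from_partition(
    partition: list[list[str]],
    nr: NonRedundantSet,
    cache: AlignmentCache,
) -> list[Pham]:
    gene_clusters = [sorted(c) for c in expand_clusters(partition, nr)]
    gene_clusters.sort(key=lambda c: (-len(c), c[0]))
    seq_of_gene = {
        gene_id: nr.sequence(digest)
        for digest in nr.digests()
        for gene_id in nr.gene_ids(digest)
    }
    phams = []
    for pham_id, members in enumerate(gene_clusters, start=1):
        sequences = {m: seq_of_gene[m] for m in members}
        phams.append(
            Pham(
                pham_id=pham_id,
                members=members,
                representative=select_representative_seq(sequences, cache),
                sequences=sequences,
            )
        )
    return phams


def _evaluate(
    partition: list[list[str]],
    nr: NonRedundantSet,
    params: ClusterParams,
    thresholds: QCThresholds,
    cache: AlignmentCache,
    elapsed: float,
) -> GridResult:
    phams = _phams_from_partition(partition, nr, cache)
    report = audit(phams, thresholds, cache)
    return GridResult(
        params=params,
        n_phams=len(phams),
        n_false_negatives=report.fn_count,
        n_false_positives=len(report.false_positives),
        fp_rate=report.fp_rate,
        runtime_seconds=elapsed,
    )


def _select_best(retained: list[tuple[int, GridResult]]) -> ClusterParams | None:
    if not retained:
        return None
    best = min(retained, key=lambda ir: (ir[1].n_false_negatives, ir[1].n_phams, ir[0]))
    return best[1].params


def run_stage1(
    genes: NonRedundantSet,
    spec: GridSpec | None = None,
    thresholds: QCThresholds = DEFAULT_QC_THRESHOLDS,
    cache: AlignmentCache | None = None,
) -> tuple[list[GridResult], ClusterParams | None]:
    """Sweep sequence–sequence parameters; keep zero-false-positive sets.

    Returns the retained results and the best parameter set (fewest false
    negatives), or ``None`` when no set survives the exclusion rule.
    """
    spec = spec or GridSpec(stage="sequence")
    cache = cache or AlignmentCache()
    retained: list[tuple[int, GridResult]] = []
    for order, params in enumerate(enumerate_grid(spec)):
        t0 = time.perf_counter()
        partition = cascade_cluster(genes, params, cache)
        result = _evaluate(
            partition, genes, params, thresholds, cache, time.perf_counter() - t0
        )
        if result.n_false_positives == 0:
            retained.append((order, result))
    return [r for _, r in retained], _select_best(retained)


def run_stage2(
    genes: NonRedundantSet,
    stage1_partition: list[list[str]],
    spec: GridSpec | None = None,
    fp_cap: float = DEFAULT_FP_CAP,
    thresholds: QCThresholds = DEFAULT_QC_THRESHOLDS,
    cache: AlignmentCache | None = None,
) -> tuple[list[GridResult], ClusterParams | None]:
    """Sweep profile–sequence parameters from fixed stage-1 phams.

    Sets are retained while the overall false-positive rate stays below
    ``fp_cap``; the best retained set has the fewest false negatives.
    """
    spec = spec or GridSpec(stage="profile")
    cache = cache or AlignmentCache()
    retained: list[tuple[int, GridResult]] = []
    for order, params in enumerate(enumerate_grid(spec)):
        t0 = time.perf_counter()
        partition = profile_merge(stage1_partition, genes, params, cache)
        result = _evaluate(
            partition, genes, params, thresholds, cache, time.perf_counter() - t0
        )
        if result.fp_rate < fp_cap:
            retained.append((order, result))
    return [r for _, r in retained], _select_best(retained)


def results_to_csv(results: list[GridResult], path: str | Path) -> None:
    """One row per parameter set, in grid order."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["cluster_mode", "steps_or_iterations", "sensitivity", "min_seq_id",
             "coverage", "evalue", "n_phams", "n_false_negatives",
             "n_false_positives", "fp_rate", "runtime_seconds"]
        )
        for r in results:
            p = r.params
            writer.writerow(
                [p.cluster_mode, max(p.cluster_steps, p.num_iterations),
                 p.sensitivity, p.min_seq_id, p.coverage, p.evalue,
                 r.n_phams, r.n_false_negatives, r.n_false_positives,
                 f"{r.fp_rate:.6f}", f"{r.runtime_seconds:.3f}"]
            )
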