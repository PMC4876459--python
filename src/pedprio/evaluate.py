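"""Evaluation protocols for network gene prioritization.

Two protocols are implemented:

* Leave-one-out cross-validation (LOOCV).  Each known disease gene is
  removed from the seed set in turn and hidden among ``n_decoys``
  (default 199) genes drawn from the genome, with inclusion probability
  proportional to coding-sequence (CDS) length — mimicking the genes a
  rare-functional-variant filter would surface, since long genes collect
  more rare variants.  The left-out gene's rank among the candidates
  measures the score's discriminative power; aggregating over left-out
  genes gives detection rates at rank cutoffs and an ROC-style curve.

* Case replication.  For a solved case with a confirmed disease gene and
  an independent seed panel, the disease gene is hidden among fresh
  decoys ``repeats`` times (default 1000); the mean percentile rank and
  the fraction of repeats landing in the top 10% summarise how reliably
  prioritization would have surfaced the gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .network import GeneNetwork, WalkParams, rank_candidates, rwr_scores

__all__ = [
    "GeneUniverse",
    "LoocvConfig",
    "LoocvResult",
    "CaseReplicationResult",
    "sample_decoys",
    "loocv",
    "case_replication",
    "roc_points",
    "read_universe",
    "write_universe",
]

DEFAULT_CUTOFFS = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90, 1.00)


class GeneUniverse:
    """The sampling frame: gene id -> CDS length (bp, positive)."""

    def __init__(self, lengths: Mapping[str, int]):
        self.genes: list[str] = sorted(lengths)
        arr = np.asarray([lengths[g] for g in self.genes], dtype=float)
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("duplicate gene ids")
        if np.any(arr <= 0):
            raise ValueError("CDS lengths must be positive")
        self.lengths = arr
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def length_of(self, gene: str) -> int:
        return int(self.lengths[self._index[gene]])


def sample_decoys(
    universe: GeneUniverse,
    n: int,
    exclude: Iterable[str] = (),
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Draw ``n`` distinct decoy genes, CDS-length-weighted, without replacement.

    Uses the exponential-sort construction (keys Exp(1)/weight, keep the
    ``n`` smallest), which is equivalent to sequential weighted draws
    with renormalisation.  Inclusion probabilities are therefore
    approximately — not exactly — proportional to length.
    """
    rng = rng or np.random.default_rng()
    excl = set(exclude)
    eligible = [i for i, g in enumerate(universe.genes) if g not in excl]
    if len(eligible) < n:
        raise ValueError(
            f"cannot draw {n} decoys from {len(eligible)} eligible genes"
        )
    idx = np.asarray(eligible)
    keys = rng.exponential(size=len(idx)) / universe.lengths[idx]
    chosen = idx[np.argsort(keys, kind="stable")[:n]]
    return [universe.genes[i] for i in chosen]


@dataclass
class LoocvConfig:
    """LOOCV protocol settings."""

    n_decoys: int = 199
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS
    repeats: int = 1  # decoy redraws per left-out gene
    seed: int | None = None
    walk: WalkParams = field(default_factory=WalkParams)
    randomize_scores: bool = False  # null calibration: i.i.d. scores per repeat

    def __post_init__(self):
        if self.n_decoys < 1:
            raise ValueError("need >= 1 decoy")
        for c in self.cutoffs:
            if not 0.0 < c <= 1.0:
                raise ValueError(f"cutoff {c} outside (0, 1]")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class LoocvResult:
    """Per-trial ranks and aggregate detection rates."""

    trials: list[dict]  # gene, repeat, rank, percentile
    cutoffs: list[float]
    detection_rates: dict[float, float]

    @property
    def mean_percentile(self) -> float:
        return float(np.mean([t["percentile"] for t in self.trials]))

    def to_dict(self) -> dict:
        return {
            "n_trials": len(self.trials),
            "mean_percentile": self.mean_percentile,
            "detection_rates": {f"{c:g}": r for c, r in self.detection_rates.items()},
            "trials": self.trials,
        }


@dataclass
class CaseReplicationResult:
    """Replication statistic for one solved case."""

    disease_gene: str
    mean_percentile: float
    top10_fraction: float
    repeats: int
    percentiles: np.ndarray

    def to_dict(self) -> dict:
        return {
            "disease_gene": self.disease_gene,
            "mean_percentile": self.mean_percentile,
            "top10_fraction": self.top10_fraction,
            "repeats": self.repeats,
        }


def _percentile_of(target: str, scores: Mapping[str, float], candidates: list[str]) -> tuple[float, float]:
    ranked = rank_candidates(scores, candidates)
    for g, _, rank, pct in ranked:
        if g == target:
            return rank, pct
    raise RuntimeError("target candidate lost during ranking")  # pragma: no cover


def _maybe_randomized(
    scores: Mapping[str, float],
    candidates: list[str],
    randomize: bool,
    rng: np.random.Generator,
) -> Mapping[str, float]:
    """Null-calibration hook: replace scores by i.i.d. Uniform(0,1) draws."""
    if not randomize:
        return scores
    return dict(zip(candidates, rng.random(len(candidates)).tolist()))


def loocv(
    network: GeneNetwork,
    seeds: Iterable[str],
    universe: GeneUniverse,
    config: LoocvConfig | None = None,
) -> LoocvResult:
    """Leave-one-out cross-validation of RWR prioritization.

    For each seed gene g: re-seed the walk with seeds minus g, hide g
    among length-weighted decoys (drawn excluding all seeds), and record
    g's rank percentile among the 1 + n_decoys candidates.  The walk is
    computed once per left-out gene; each repeat redraws decoys only.
    """
    cfg = config or LoocvConfig()
    seed_list = sorted(set(seeds))
    if len(seed_list) < 2:
        raise ValueError("LOOCV needs >= 2 seed genes")
    rng = np.random.default_rng(cfg.seed)
    trials: list[dict] = []
    for gene in seed_list:
        remaining = [s for s in seed_list if s != gene]
        sv = rwr_scores(network, remaining, cfg.walk)
        score_map = sv.as_dict()
        for rep in range(cfg.repeats):
            decoys = sample_decoys(
                universe, cfg.n_decoys, exclude=set(seed_list), rng=rng
            )
            candidates = [gene] + decoys
            eff = _maybe_randomized(score_map, candidates, cfg.randomize_scores, rng)
            rank, pct = _percentile_of(gene, eff, candidates)
            trials.append(
                {"gene": gene, "repeat": rep, "rank": rank, "percentile": pct}
            )
    cutoffs = [float(c) for c in cfg.cutoffs]
    pcts = np.asarray([t["percentile"] for t in trials])
    rates = {c: float(np.mean(pcts <= c)) for c in cutoffs}
    return LoocvResult(trials=trials, cutoffs=cutoffs, detection_rates=rates)


def case_replication(
    network: GeneNetwork,
    disease_gene: str,
    seeds: Iterable[str],
    universe: GeneUniverse,
    repeats: int = 1000,
    n_decoys: int = 199,
    rng: np.random.Generator | int | None = None,
    walk: WalkParams | None = None,
) -> CaseReplicationResult:
    """Replicate a solved case: hide the confirmed gene among fresh decoys.

    The seed panel must not contain the disease gene (that would leak
    the answer).  One walk is computed; each of ``repeats`` independent
    decoy draws re-ranks the disease gene among 1 + n_decoys candidates.
    """
    seed_list = sorted(set(seeds))
    if disease_gene in seed_list:
        raise ValueError(f"disease gene {disease_gene!r} must not be among the seeds")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sv = rwr_scores(network, seed_list, walk or WalkParams())
    score_map = sv.as_dict()
    pcts = np.empty(repeats)
    for i in range(repeats):
        decoys = sample_decoys(
            universe, n_decoys, exclude=set(seed_list) | {disease_gene}, rng=rng
        )
        _, pcts[i] = _percentile_of(disease_gene, score_map, [disease_gene] + decoys)
    return CaseReplicationResult(
        disease_gene=disease_gene,
        mean_percentile=float(pcts.mean()),
        top10_fraction=float(np.mean(pcts <= 0.10)),
        repeats=repeats,
        percentiles=pcts,
    )


def roc_points(result: LoocvResult) -> list[tuple[float, float]]:
    """ROC-style curve: detection rate (sensitivity) vs rank cutoff (1 - specificity).

    Returns points from (0, 0) to (1, 1), non-decreasing in both
    coordinates, evaluated at the configured cutoffs.
    """
    pcts = np.asarray([t["percentile"] for t in result.trials])
    pts = [(0.0, 0.0)]
    for c in sorted(result.cutoffs):
        pts.append((float(c), float(np.mean(pcts <= c))))
    if pts[-1][0] < 1.0:
        pts.append((1.0, 1.0))
    return pts


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_universe(path: str | Path) -> GeneUniverse:
    """Read a 2-column TSV (gene id, CDS length in bp)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns (gene, cds_length)")
            try:
                lengths[parts[0]] = int(parts[1])
            except ValueError:
                raise ValueError(f"{path}:{ln}: malformed length {parts[1]!r}") from None
    return GeneUniverse(lengths)


def write_universe(universe: GeneUniverse, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene\tcds_length\n")
        for g, ln in zip(universe.genes, universe.lengths):
            fh.write(f"{g}\t{int(ln)}\n")
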