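"""Synthetic-data generators with known ground truth.

The pipeline's real inputs — SNP-array IBD probability tracks for a
large kindred, a patient's annotated exome, a functional gene network —
are emulated here with planted truth so every downstream step can be
validated:

* **Gene dropping.**  Founder haplotypes are uniquely labelled and
  transmitted through the pedigree; each meiosis places crossovers as a
  Poisson process on the genetic (cM) map (Haldane model, no
  interference).  The true pairwise IBD state at a marker is the number
  of allele positions carrying the same founder label.
* **Probability tracks.**  The true state receives probability
  ``1 - eps``, the other two states ``eps/2`` each.  Because
  ``1 - eps > 0.5`` for any ``eps < 0.5``, threshold-0.5 segment calling
  recovers the true state runs exactly.
* **Variant table.**  Background variants carry mixed attributes (some
  common, some non-functional, some weakly conserved, some not carried
  by the proband); exactly one planted causal variant passes every
  filter and lies in a region truly shared IBD by both patients and by
  no unaffected sib.
* **Network.**  A two-block stochastic block model: a dense functional
  module holding the seed genes and the disease gene, against a sparse
  background.

The default configuration emulates the study design this pipeline
targets: two affected relatives at kinship 1/32 (first cousins once
removed), each with an unaffected elder sib, on a scaled-down genome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .evaluate import GeneUniverse, write_universe
from .intervals import (
    GeneticMap,
    IbdTrack,
    RegionSet,
    intersect,
    subtract,
    union,
    write_bed,
    write_genetic_map,
    write_ibd_table,
)
from .network import GeneNetwork, build_network, write_edge_list
from .variants import VariantRecord, FUNCTIONAL_CLASSES, write_variant_table

__all__ = [
    "Individual",
    "SimPedigree",
    "SimConfig",
    "TruthBundle",
    "SyntheticBundle",
    "default_kindred",
    "gene_drop",
    "true_state_regions",
    "emit_tracks",
    "plant_variants",
    "make_network",
    "make_universe",
    "simulate_bundle",
    "write_bundle",
]

CM_PER_MORGAN = 100.0
BP_PER_CM = 1_000_000  # fixed physical:genetic scaling of the synthetic map


@dataclass(frozen=True)
class Individual:
    id: str
    father: str | None = None
    mother: str | None = None
    sex: str = "U"  # M / F / U
    affected: bool = False
    genotyped: bool = False


class SimPedigree:
    """A pedigree as a list of individuals; validated to be acyclic."""

    def __init__(self, individuals: Sequence[Individual]):
        self.members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.members:
                raise ValueError(f"duplicate individual id {ind.id!r}")
            self.members[ind.id] = ind
        for ind in self.members.values():
            if (ind.father is None) != (ind.mother is None):
                raise ValueError(f"{ind.id}: non-founder must have both parents")
            for p in (ind.father, ind.mother):
                if p is not None and p not in self.members:
                    raise ValueError(f"{ind.id}: parent {p!r} not in pedigree")
        self.order = self._topological_order()

    def _topological_order(self) -> list[str]:
        state: dict[str, int] = {}
        order: list[str] = []

        def visit(i: str, stack: tuple[str, ...]):
            if i in stack:
                raise ValueError(f"pedigree cycle involving {i!r}")
            if state.get(i) == 2:
                return
            ind = self.members[i]
            for p in (ind.father, ind.mother):
                if p is not None:
                    visit(p, stack + (i,))
            state[i] = 2
            order.append(i)

        for i in self.members:
            visit(i, ())
        return order

    @property
    def founders(self) -> list[str]:
        return [i for i, ind in self.members.items() if ind.father is None]

    @property
    def genotyped(self) -> list[str]:
        return [i for i, ind in self.members.items() if ind.genotyped]


def default_kindred() -> SimPedigree:
    """The default emulated kindred branch.

    Two affected relatives, ``P1`` (proband-like, generation III) and
    ``P2`` (exome-sequenced, generation IV), related as first cousins
    once removed (kinship coefficient 1/32), each with one unaffected
    elder sib available for IBD-based exclusion.
    """
    return SimPedigree([
        Individual("A1", sex="M"), Individual("A2", sex="F"),
        Individual("B1", "A1", "A2", "M"), Individual("B1_SP", sex="F"),
        Individual("B2", "A1", "A2", "F"), Individual("B2_SP", sex="M"),
        Individual("P1_SIB", "B1", "B1_SP", "M", affected=False, genotyped=True),
        Individual("P1", "B1", "B1_SP", "M", affected=True, genotyped=True),
        Individual("C1", "B2_SP", "B2", "F"), Individual("C1_SP", sex="M"),
        Individual("P2_SIB", "C1_SP", "C1", "F", affected=False, genotyped=True),
        Individual("P2", "C1_SP", "C1", "M", affected=True, genotyped=True),
    ])


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic generator.

    Genome and marker grid are scaled down from a human SNP-linkage
    panel; network and exome sizes are scaled to keep a full pipeline
    run fast while preserving every qualitative feature the filters and
    the walk rely on.
    """

    chrom_lengths_cm: Mapping[str, float] = field(
        default_factory=lambda: {f"chr{i}": 120.0 for i in range(1, 11)}
    )
    marker_spacing_cm: float = 1.0
    epsilon: float = 0.05  # IBD-probability confusion noise

    n_genes: int = 400
    module_size: int = 40
    n_seeds: int = 20
    p_in: float = 0.30
    p_out: float = 0.01

    cds_log_mean: float = 7.2  # lognormal CDS lengths, median ~1.3 kb
    cds_log_sd: float = 0.8

    n_background_variants: int = 200
    panels: tuple[str, ...] = ("population", "inhouse")
    p_common: float = 0.30        # AF >= frequency threshold in some panel
    p_nonfunctional: float = 0.25  # consequence class 'other'
    p_low_gerp: float = 0.25       # SNV with GERP below the conservation cutoff
    p_proband_carrier: float = 0.50
    p_absent_from_panels: float = 0.50  # rare variant seen in no panel at all
    frequency_threshold: float = 0.005
    gerp_min: float = 2.0
    gerp_max: float = 6.18

    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError(f"epsilon must be in [0, 0.5), got {self.epsilon}")
        if self.marker_spacing_cm <= 0:
            raise ValueError("marker spacing must be > 0")
        if not self.p_in > self.p_out:
            raise ValueError("module density p_in must exceed background p_out")
        if self.n_seeds + 1 > self.module_size:
            raise ValueError("module must hold the seeds plus the disease gene")
        if self.module_size > self.n_genes:
            raise ValueError("module larger than gene count")

    def marker_positions_cm(self, chrom: str) -> np.ndarray:
        L = self.chrom_lengths_cm[chrom]
        return np.arange(0.0, L + 1e-9, self.marker_spacing_cm)

    def genetic_map(self) -> GeneticMap:
        anchors = {}
        for chrom in self.chrom_lengths_cm:
            cm = self.marker_positions_cm(chrom)
            bp = (cm * BP_PER_CM).astype(np.int64) + 1
            anchors[chrom] = list(zip(bp.tolist(), cm.tolist()))
        return GeneticMap(anchors)

    def chrom_length_bp(self, chrom: str) -> int:
        return int(self.chrom_lengths_cm[chrom] * BP_PER_CM) + 1


@dataclass
class TruthBundle:
    """Ground truth tied to one simulated dataset."""

    true_states: dict[tuple[str, str], dict[str, np.ndarray]]
    patient_shared: RegionSet
    sib_excluded: RegionSet  # patient-shared regions removed by sib sharing
    candidate: RegionSet     # patient_shared minus sib_excluded
    causal_chrom: str = ""
    causal_pos: int = 0
    causal_gene: str = ""
    module_genes: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "causal": {
                "chrom": self.causal_chrom,
                "pos": self.causal_pos,
                "gene": self.causal_gene,
            },
            "module_genes": self.module_genes,
            "patient_shared_bp": self.patient_shared.total_length(),
            "candidate_bp": self.candidate.total_length(),
            "true_states": {
                "|".join(pair): {
                    chrom: arr.tolist() for chrom, arr in per_chrom.items()
                }
                for pair, per_chrom in self.true_states.items()
            },
        }


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

def _meiosis(
    hap0: np.ndarray, hap1: np.ndarray, cm: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Transmit one gamete: Poisson crossovers on the cM axis, Haldane model."""
    L = float(cm[-1] - cm[0]) if len(cm) > 1 else 0.0
    n_x = rng.poisson(L / CM_PER_MORGAN)
    xpos = np.sort(rng.uniform(cm[0], cm[0] + L, n_x)) if n_x else np.empty(0)
    phase = (rng.integers(2) + np.searchsorted(xpos, cm, side="right")) % 2
    return np.where(phase == 0, hap0, hap1)


def gene_drop(
    pedigree: SimPedigree,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[dict, dict[tuple[str, str], dict[str, np.ndarray]]]:
    """Drop uniquely-labelled founder haplotypes through the pedigree.

    Returns the per-individual haplotype-label mosaics and, for every
    pair of genotyped individuals, the true IBD state (0/1/2) at each
    marker: the number of allele positions sharing a founder label.
    """
    haplotypes: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    label = 0
    for ind_id in pedigree.order:
        ind = pedigree.members[ind_id]
        haplotypes[ind_id] = {}
        if ind.father is None:
            l0, l1 = label, label + 1
            label += 2
            for chrom in config.chrom_lengths_cm:
                m = len(config.marker_positions_cm(chrom))
                haplotypes[ind_id][chrom] = (
                    np.full(m, l0, dtype=np.int64),
                    np.full(m, l1, dtype=np.int64),
                )
        else:
            for chrom in config.chrom_lengths_cm:
                cm = config.marker_positions_cm(chrom)
                pat = _meiosis(*haplotypes[ind.father][chrom], cm, rng)
                mat = _meiosis(*haplotypes[ind.mother][chrom], cm, rng)
                haplotypes[ind_id][chrom] = (pat, mat)

    genotyped = sorted(pedigree.genotyped)
    states: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for i, a in enumerate(genotyped):
        for b in genotyped[i + 1:]:
            pair = (a, b)
            states[pair] = {}
            for chrom in config.chrom_lengths_cm:
                a0, a1 = haplotypes[a][chrom]
                b0, b1 = haplotypes[b][chrom]
                # no inbreeding in supported pedigrees: within-individual
                # labels differ, so simple pairwise equality counts IBD pairs
                st = (
                    (a0 == b0).astype(np.int8) + (a0 == b1)
                    + (a1 == b0) + (a1 == b1)
                )
                states[pair][chrom] = np.minimum(st, 2).astype(np.int8)
    return haplotypes, states


def true_state_regions(
    states: Mapping[str, np.ndarray], config: SimConfig, min_state: int = 1
) -> RegionSet:
    """Regions spanned by runs of markers with true IBD state >= ``min_state``.

    Uses the same inclusive first-to-last-marker span convention as the
    probabilistic segment caller, so noiseless tracks reproduce it.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, st in states.items():
        share = np.asarray(st) >= min_state
        if not share.any():
            continue
        cm = config.marker_positions_cm(chrom)
        bp = (cm * BP_PER_CM).astype(np.int64) + 1
        padded = np.concatenate(([False], share, [False]))
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(~padded[1:] & padded[:-1]) - 1
        out[chrom] = [(int(bp[s]) - 1, int(bp[e])) for s, e in zip(starts, ends)]
    return RegionSet(out)


def emit_tracks(
    pair: tuple[str, str],
    states: Mapping[str, np.ndarray],
    config: SimConfig,
    epsilon: float | None = None,
) -> IbdTrack:
    """Turn true IBD states into a probability track with confusion noise.

    The true state gets probability ``1 - eps``; each other state gets
    ``eps / 2``.  Since ``1 - eps > 0.5`` whenever ``eps < 0.5``, segment
    calling at threshold 0.5 recovers the true runs exactly.
    """
    eps = config.epsilon if epsilon is None else epsilon
    if not 0.0 <= eps < 0.5:
        raise ValueError(f"epsilon must be in [0, 0.5), got {eps}")
    markers: dict[str, np.ndarray] = {}
    for chrom, st in states.items():
        st = np.asarray(st)
        cm = config.marker_positions_cm(chrom)
        bp = (cm * BP_PER_CM).astype(np.int64) + 1
        probs = np.full((len(st), 3), eps / 2.0)
        probs[np.arange(len(st)), st] = 1.0 - eps
        markers[chrom] = np.column_stack([bp.astype(float), probs])
    return IbdTrack(pair, markers)


# ---------------------------------------------------------------------------
# Variants, network, universe
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))

def _random_snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    i = rng.integers(4)
    j = (i + 1 + rng.integers(3)) % 4
    return str(_BASES[i]), str(_BASES[j])


def place_genes(
    genes: Sequence[str], config: SimConfig, rng: np.random.Generator
) -> dict[str, tuple[str, int]]:
    """Assign each gene a point position, uniform over the physical genome."""
    chroms = list(config.chrom_lengths_cm)
    lens = np.array([config.chrom_length_bp(c) for c in chroms], dtype=float)
    probs = lens / lens.sum()
    out = {}
    for g in genes:
        c = chroms[rng.choice(len(chroms), p=probs)]
        out[g] = (c, int(rng.integers(1, config.chrom_length_bp(c) + 1)))
    return out


def plant_variants(
    gene_positions: Mapping[str, tuple[str, int]],
    causal_gene: str,
    config: SimConfig,
    rng: np.random.Generator,
    exome_sample: str = "P2",
    proband: str = "P1",
) -> tuple[list[VariantRecord], tuple]:
    """Generate the exome variant table with one planted causal variant.

    Background variants are drawn from the exome-sequenced sample (so it
    always carries them) with independent attribute mixtures; the causal
    variant is a rare, conserved missense SNV at the causal gene's
    position, carried by both patients and seen in no panel.  Returns
    the table and the causal variant's (chrom, pos, ref, alt) key.
    """
    functional = sorted(FUNCTIONAL_CLASSES)
    snv_classes = sorted(FUNCTIONAL_CLASSES - {"frameshift", "inframe_indel"})
    records: list[VariantRecord] = []
    background_genes = [g for g in sorted(gene_positions) if g != causal_gene]
    for k in range(config.n_background_variants):
        gene = background_genes[rng.integers(len(background_genes))]
        chrom, pos = gene_positions[gene]
        if rng.random() < config.p_nonfunctional:
            cls = "other"
        else:
            cls = functional[rng.integers(len(functional))]
        is_indel = cls in ("frameshift", "inframe_indel")
        if is_indel:
            ref, alt = "A", "AT"
            gerp = None
        else:
            ref, alt = _random_snv_alleles(rng)
            if rng.random() < config.p_low_gerp:
                gerp = float(rng.uniform(-3.0, config.gerp_min))
            else:
                gerp = float(rng.uniform(config.gerp_min, config.gerp_max))
        freqs: dict[str, float] = {}
        if rng.random() < config.p_common:
            hot = config.panels[rng.integers(len(config.panels))]
            for panel in config.panels:
                if panel == hot:
                    freqs[panel] = float(rng.uniform(config.frequency_threshold, 0.2))
                elif rng.random() < 0.5:
                    freqs[panel] = float(rng.uniform(0.0, 0.2))
        elif rng.random() >= config.p_absent_from_panels:
            panel = config.panels[rng.integers(len(config.panels))]
            freqs[panel] = float(
                rng.uniform(0.0, config.frequency_threshold * 0.999)
            )
        genotypes = {
            exome_sample: 1,
            proband: 1 if rng.random() < config.p_proband_carrier else 0,
        }
        records.append(
            VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                consequence=cls, frequencies=freqs, gerp=gerp,
                genotypes=genotypes,
            )
        )
    c_chrom, c_pos = gene_positions[causal_gene]
    ref, alt = _random_snv_alleles(rng)
    causal = VariantRecord(
        chrom=c_chrom, pos=c_pos, ref=ref, alt=alt, gene=causal_gene,
        consequence="missense_snv", frequencies={},
        gerp=float(rng.uniform(config.gerp_min + 0.5, config.gerp_max)),
        genotypes={exome_sample: 1, proband: 1, "P1_SIB": 0, "P2_SIB": 0},
    )
    records.append(causal)
    records.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    return records, causal.key


def make_network(
    genes: Sequence[str],
    module_genes: Sequence[str],
    p_in: float,
    p_out: float,
    rng: np.random.Generator,
    weight: float = 1.0,
) -> GeneNetwork:
    """Two-block stochastic block model with unit edge weights.

    Genes inside ``module_genes`` are wired with probability ``p_in``,
    every other pair with probability ``p_out``.
    """
    genes = list(genes)
    in_module = np.isin(genes, list(module_genes))
    n = len(genes)
    edges = []
    # vectorised upper-triangle Bernoulli draws, row by row
    for i in range(n - 1):
        m = n - i - 1
        p = np.where(in_module[i] & in_module[i + 1:], p_in, p_out)
        hits = np.flatnonzero(rng.random(m) < p)
        for j in hits:
            edges.append((genes[i], genes[i + 1 + j], weight))
    return build_network(edges, extra_nodes=genes)


def make_universe(
    genes: Sequence[str], config: SimConfig, rng: np.random.Generator
) -> GeneUniverse:
    """Lognormal CDS lengths (bp), floored at 1."""
    lengths = rng.lognormal(config.cds_log_mean, config.cds_log_sd, len(genes))
    return GeneUniverse(
        {g: max(1, int(round(l))) for g, l in zip(genes, lengths)}
    )


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    """Everything one simulated study produces, plus its ground truth."""

    config: SimConfig
    pedigree: SimPedigree
    genetic_map: GeneticMap
    tracks: list[IbdTrack]
    variants: list[VariantRecord]
    network: GeneNetwork
    seeds: list[str]
    universe: GeneUniverse
    gene_positions: dict[str, tuple[str, int]]
    truth: TruthBundle

    @property
    def patient_pair(self) -> tuple[str, str]:
        return ("P1", "P2")

    def track_for(self, a: str, b: str) -> IbdTrack:
        key = tuple(sorted((a, b)))
        for t in self.tracks:
            if t.pair == key:
                return t
        raise KeyError(f"no track for pair {key}")


def simulate_bundle(
    config: SimConfig | None = None, seed: int | None = None, max_tries: int = 100
) -> SyntheticBundle:
    """Simulate one complete study with planted ground truth.

    Gene drops are retried until the two patients share at least one
    region that survives the sib exclusion — the configuration where a
    causal variant can be planted (expected for kinship-1/32 relatives
    on the default genome; retries are rare).
    """
    config = config or SimConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    pedigree = default_kindred()
    gmap = config.genetic_map()

    truth = None
    for _ in range(max_tries):
        _, states = gene_drop(pedigree, config, rng)
        shared = true_state_regions(states[("P1", "P2")], config)
        excluded = RegionSet()
        for sib in ("P1_SIB", "P2_SIB"):
            s1 = true_state_regions(states[tuple(sorted((sib, "P1")))], config)
            s2 = true_state_regions(states[tuple(sorted((sib, "P2")))], config)
            excluded = union(excluded, intersect(shared, intersect(s1, s2)))
        candidate = subtract(shared, excluded)
        if not candidate.is_empty():
            truth = TruthBundle(
                true_states=states,
                patient_shared=shared,
                sib_excluded=excluded,
                candidate=candidate,
            )
            break
    if truth is None:
        raise RuntimeError(
            f"no sib-surviving shared region in {max_tries} gene drops"
        )

    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    module = genes[: config.module_size]
    disease_gene = module[0]
    seeds = module[1 : 1 + config.n_seeds]
    truth.module_genes = module
    truth.causal_gene = disease_gene

    network = make_network(genes, module, config.p_in, config.p_out, rng)
    universe = make_universe(genes, config, rng)
    gene_positions = place_genes(genes, config, rng)

    # plant the disease gene inside the candidate region: pick a random
    # covered base, weighted by interval length
    ivs = [(c, s, e) for c, arr in truth.candidate.items() for s, e in arr]
    lens = np.array([e - s for _, s, e in ivs], dtype=float)
    c, s, e = ivs[rng.choice(len(ivs), p=lens / lens.sum())]
    gene_positions[disease_gene] = (c, int(rng.integers(s, e)) + 1)

    variants, causal_key = plant_variants(
        gene_positions, disease_gene, config, rng
    )
    truth.causal_chrom, truth.causal_pos = causal_key[0], causal_key[1]

    pairs = [("P1", "P2")] + [
        tuple(sorted((sib, p)))
        for sib in ("P1_SIB", "P2_SIB")
        for p in ("P1", "P2")
    ]
    tracks = [
        emit_tracks(pair, truth.true_states[tuple(sorted(pair))], config)
        for pair in pairs
    ]

    return SyntheticBundle(
        config=config,
        pedigree=pedigree,
        genetic_map=gmap,
        tracks=tracks,
        variants=variants,
        network=network,
        seeds=seeds,
        universe=universe,
        gene_positions=gene_positions,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write every pipeline input (plus truth.json) under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ibd": out / "ibd.tsv",
        "map": out / "map.tsv",
        "variants": out / "variants.tsv",
        "network": out / "network.tsv",
        "seeds": out / "seeds.txt",
        "universe": out / "universe.tsv",
        "truth": out / "truth.json",
        "candidate_bed": out / "true_candidate_regions.bed",
    }
    write_ibd_table(bundle.tracks, paths["ibd"])
    write_genetic_map(bundle.genetic_map, paths["map"])
    write_variant_table(bundle.variants, paths["variants"])
    write_edge_list(bundle.network, paths["network"])
    paths["seeds"].write_text("".join(f"{g}\n" for g in bundle.seeds))
    write_universe(bundle.universe, paths["universe"])
    write_bed(bundle.truth.candidate, paths["candidate_bed"])
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth.to_json_dict(), fh, indent=1)
    return paths
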