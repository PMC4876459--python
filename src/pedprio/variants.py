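"""Ultra-rare functional-variant filter cascade.

Implements the exome filtering used to reduce a single patient's
annotated variant table to candidate causal variants for a dominant
disorder:

1. frequency  — drop variants with allele frequency >= 0.5% in *any*
   reference panel (population databases or in-house exomes);
2. consequence — keep only missense, nonsense, frameshift, in-frame
   indel and splice-site variants;
3. conservation — drop SNVs that are not evolutionarily conserved
   (GERP < 2.0); indels are exempt since GERP is a per-site
   substitution score;
4. regions — keep variants inside candidate shared-IBD regions;
5. carrier — keep variants carried (or not) by a named sample, e.g. a
   second affected relative genotyped by Sanger.

All filters are pointwise predicates on a single record, so any stage
ordering yields the same survivor set; the report orders them as above.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import RegionSet

__all__ = [
    "CONSEQUENCE_CLASSES",
    "FUNCTIONAL_CLASSES",
    "INDEL_CLASSES",
    "VariantRecord",
    "FilterReport",
    "CascadeConfig",
    "filter_frequency",
    "filter_consequence",
    "filter_conservation",
    "filter_regions",
    "filter_carrier",
    "run_cascade",
    "read_variant_table",
    "write_variant_table",
]

CONSEQUENCE_CLASSES = frozenset(
    {"missense_snv", "nonsense", "frameshift", "inframe_indel", "splice_site", "other"}
)
#: the five functional classes retained by the consequence filter
FUNCTIONAL_CLASSES = frozenset(
    {"missense_snv", "nonsense", "frameshift", "inframe_indel", "splice_site"}
)
#: classes exempt from the per-site conservation (GERP) filter
INDEL_CLASSES = frozenset({"frameshift", "inframe_indel"})


@dataclass(frozen=True)
class VariantRecord:
    """One annotated, bi-allelic exonic variant.

    ``frequencies`` maps panel name -> allele frequency; a panel absent
    from the map means the variant was not observed there.  ``genotypes``
    maps sample id -> alt-allele count (0/1/2); a missing sample means
    no genotype is available.  ``gerp`` is None for records where the
    score is undefined (typically indels).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    consequence: str
    frequencies: Mapping[str, float] = field(default_factory=dict)
    gerp: float | None = None
    genotypes: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position {self.pos} < 1 (positions are 1-based)")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence class {self.consequence!r}")
        for panel, f in self.frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"panel {panel!r}: frequency {f} outside [0, 1]")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return self.consequence in INDEL_CLASSES


@dataclass
class FilterReport:
    """Per-stage survivor accounting for one cascade run."""

    stages: list[tuple[str, int, int]]  # (name, n_in, n_out)
    survivors: list[VariantRecord]
    flagged_missing_genotype: list[tuple] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        """Distinct genes among the survivors, in survivor order."""
        seen: dict[str, None] = {}
        for v in self.survivors:
            seen.setdefault(v.gene)
        return list(seen)

    @property
    def n_survivors(self) -> int:
        return len(self.survivors)

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"stage": s, "n_in": a, "n_out": b} for s, a, b in self.stages
            ],
            "n_survivors": self.n_survivors,
            "n_genes": len(self.genes),
            "survivors": [
                {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                 "gene": v.gene, "consequence": v.consequence}
                for v in self.survivors
            ],
            "flagged_missing_genotype": [list(k) for k in self.flagged_missing_genotype],
        }


def filter_frequency(
    variants: Sequence[VariantRecord], threshold: float = 0.005
) -> list[VariantRecord]:
    """Drop variants with allele frequency >= ``threshold`` in any panel.

    A variant absent from every panel passes: absence of evidence of
    commonness cannot certify commonness.
    """
    if threshold < 0:
        raise ValueError(f"frequency threshold must be >= 0, got {threshold}")
    return [
        v for v in variants
        if all(f < threshold for f in v.frequencies.values())
    ]


def filter_consequence(variants: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Keep only the five functional consequence classes."""
    return [v for v in variants if v.consequence in FUNCTIONAL_CLASSES]


def filter_conservation(
    variants: Sequence[VariantRecord], gerp_min: float = 2.0
) -> list[VariantRecord]:
    """Drop non-conserved SNVs (GERP < ``gerp_min``); indels are exempt.

    An SNV with no GERP score is dropped: conservation cannot be
    certified, the mirror of the frequency filter's asymmetry.
    """
    out = []
    for v in variants:
        if v.is_indel:
            out.append(v)
        elif v.gerp is not None and v.gerp >= gerp_min:
            out.append(v)
    return out


def filter_regions(
    variants: Sequence[VariantRecord], regions: RegionSet
) -> list[VariantRecord]:
    """Keep variants whose 1-based position falls inside ``regions``."""
    return [v for v in variants if regions.contains(v.chrom, v.pos)]


def filter_carrier(
    variants: Sequence[VariantRecord],
    sample_id: str,
    require_alt: bool = True,
    flagged: list | None = None,
) -> list[VariantRecord]:
    """Keep variants by the named sample's carrier status.

    With ``require_alt`` the sample must carry >= 1 alt allele; without
    it the sample must be homozygous reference.  A variant with no
    genotype for the sample is retained and its key appended to
    ``flagged`` (it cannot be excluded on missing evidence).
    """
    out = []
    for v in variants:
        gt = v.genotypes.get(sample_id)
        if gt is None:
            if flagged is not None:
                flagged.append(v.key)
            out.append(v)
        elif (gt >= 1) == require_alt:
            out.append(v)
    return out


@dataclass
class CascadeConfig:
    """Thresholds and optional stages of the filter cascade."""

    frequency_threshold: float = 0.005
    gerp_min: float = 2.0
    regions: RegionSet | None = None
    carrier_sample: str | None = None
    carrier_require_alt: bool = True


def run_cascade(
    variants: Sequence[VariantRecord], config: CascadeConfig | None = None
) -> FilterReport:
    """Run the full cascade and account for survivors at every stage.

    Stage order: frequency -> consequence -> conservation, then the
    optional region restriction and carrier check.  Because every stage
    is a pointwise predicate the final survivor set is order-invariant;
    only the per-stage counts depend on the order.
    """
    cfg = config or CascadeConfig()
    stages: list[tuple[str, int, int]] = []
    flagged: list[tuple] = []
    cur = list(variants)

    def step(name, fn):
        nonlocal cur
        n_in = len(cur)
        cur = fn(cur)
        stages.append((name, n_in, len(cur)))

    step("frequency", lambda vs: filter_frequency(vs, cfg.frequency_threshold))
    step("consequence", filter_consequence)
    step("conservation", lambda vs: filter_conservation(vs, cfg.gerp_min))
    if cfg.regions is not None:
        step("regions", lambda vs: filter_regions(vs, cfg.regions))
    if cfg.carrier_sample is not None:
        step(
            "carrier",
            lambda vs: filter_carrier(
                vs, cfg.carrier_sample, cfg.carrier_require_alt, flagged
            ),
        )
    return FilterReport(stages=stages, survivors=cur, flagged_missing_genotype=flagged)


# ---------------------------------------------------------------------------
# I/O — TSV with packed frequency/genotype columns
# ---------------------------------------------------------------------------

def _pack(mapping: Mapping, fmt) -> str:
    if not mapping:
        return "."
    return ";".join(f"{k}={fmt(v)}" for k, v in sorted(mapping.items()))


def _unpack(text: str, cast):
    if text in (".", "", "nan"):
        return {}
    out = {}
    for item in text.split(";"):
        k, _, v = item.partition("=")
        out[k] = cast(v)
    return out


def write_variant_table(variants: Iterable[VariantRecord], path: str | Path) -> None:
    rows = [
        {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "consequence": v.consequence,
            "gerp": "." if v.gerp is None else f"{v.gerp:.6g}",
            "frequencies": _pack(v.frequencies, lambda f: f"{f:.8g}"),
            "genotypes": _pack(v.genotypes, str),
        }
        for v in variants
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "gene", "consequence",
                 "gerp", "frequencies", "genotypes"],
    ).to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"chrom", "pos", "ref", "alt", "gene", "consequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), 2):
        try:
            gerp = None if row.gerp in (".", "") else float(row.gerp)
            out.append(
                VariantRecord(
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    gene=row.gene,
                    consequence=row.consequence,
                    frequencies=_unpack(getattr(row, "frequencies", "."), float),
                    gerp=gerp,
                    genotypes=_unpack(getattr(row, "genotypes", "."), int),
                )
            )
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"{path}:{i}: {exc}") from None
    return out
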