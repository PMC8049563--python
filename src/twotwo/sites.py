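"""Turn per-site genotype records into configuration counts.

The primary input is a headered tab-separated table with columns
``chrom  pos  ancestral  d1  d2`` and optionally ``d_out`` — one row per
investigated site (monomorphic sites included; they are what makes
``m_tot`` meaningful), with ``d1``/``d2`` the derived-allele counts in the
two diploid individuals and ``d_out`` the count in an outgroup individual.
Coordinates are 1-based.  A minimal VCF ingestion path (two sample columns
plus an ancestral-allele INFO tag) is a convenience wrapper producing the
same record stream.

Counts are tallied per contiguous genomic block (default 5 Mb physical
span) to feed the weighted block jackknife.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ConfigCounts, ModelError

__all__ = [
    "SiteRecord",
    "BlockedCounts",
    "polarize_site",
    "tally_counts",
    "ascertained_tally",
    "read_site_table",
    "read_vcf_sites",
    "read_counts_file",
    "write_counts_file",
]

DEFAULT_BLOCK_SIZE = 5_000_000

_MISSING_ALLELES = {".", "N", "n", "", "*"}


@dataclass(frozen=True)
class SiteRecord:
    """One polarized site: derived-allele counts per diploid individual."""

    chrom: str
    pos: int
    ancestral: str
    d1: int
    d2: int
    d_out: int | None = None
    valid: bool = True
    reason: str | None = None


@dataclass(frozen=True)
class BlockedCounts:
    """Per-block configuration counts plus their total.

    Blocks are ordered contiguous genomic chunks; the block counts must sum
    to the total (validated on construction).
    """

    blocks: list[tuple[str, ConfigCounts]]
    total: ConfigCounts
    dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.blocks:
            raise ModelError("BlockedCounts needs at least one block")
        m = np.zeros((3, 3))
        for _, c in self.blocks:
            m += c.m
        if not np.allclose(m, self.total.m, rtol=1e-9, atol=1e-6):
            raise ModelError("block counts do not sum to the total")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def leave_one_out(self, index: int) -> ConfigCounts:
        """Total counts minus block ``index``."""
        return self.total - self.blocks[index][1]


def polarize_site(genotype1: str, genotype2: str, ancestral: str) -> tuple[int, int] | None:
    """Derived-allele counts for two diploid genotypes, or ``None`` if the
    site is unusable (missing call, or more than one derived allele).

    Genotypes are allele strings like ``"A/G"`` or ``"A|G"``.
    """
    d1, d2, reason = _polarize(genotype1, genotype2, ancestral)
    return None if reason else (d1, d2)


def _polarize(genotype1: str, genotype2: str, ancestral: str) -> tuple[int, int, str | None]:
    if ancestral in _MISSING_ALLELES:
        return 0, 0, "missing_ancestral"
    alleles = []
    for gt in (genotype1, genotype2):
        parts = gt.replace("|", "/").split("/")
        if len(parts) != 2:
            return 0, 0, "not_diploid"
        if any(a in _MISSING_ALLELES for a in parts):
            return 0, 0, "missing_genotype"
        alleles.append(parts)
    derived = {a for parts in alleles for a in parts if a != ancestral}
    if len(derived) > 1:
        return 0, 0, "multi_allelic"
    d1 = sum(a != ancestral for a in alleles[0])
    d2 = sum(a != ancestral for a in alleles[1])
    return d1, d2, None


def _check_record(rec: SiteRecord) -> str | None:
    if not rec.valid:
        return rec.reason or "flagged_invalid"
    for d in (rec.d1, rec.d2):
        if d not in (0, 1, 2):
            return "count_out_of_range"
    if rec.d_out is not None and rec.d_out not in (0, 1, 2):
        return "count_out_of_range"
    return None


def _tally(records, block_size, ascertain) -> BlockedCounts:
    blocks: dict[str, np.ndarray] = {}
    order: list[str] = []
    dropped: Counter = Counter()
    last_key: tuple[str, int] | None = None
    total = np.zeros((3, 3))
    n_records = 0

    for rec in records:
        n_records += 1
        key = (rec.chrom, rec.pos)
        if last_key is not None and rec.chrom == last_key[0] and rec.pos < last_key[1]:
            raise ModelError(
                f"site records are not sorted: {rec.chrom}:{rec.pos} after "
                f"{last_key[0]}:{last_key[1]}"
            )
        last_key = key
        reason = _check_record(rec)
        if reason:
            dropped[reason] += 1
            continue
        if ascertain is not None:
            if rec.d_out is None:
                raise ModelError("ascertained tally requires a d_out column on every site")
            needed = 1 if ascertain == "any" else 2
            if rec.d_out < needed:
                continue
        start = (rec.pos - 1) // block_size * block_size
        bid = f"{rec.chrom}:{start + 1}-{start + block_size}"
        if bid not in blocks:
            blocks[bid] = np.zeros((3, 3))
            order.append(bid)
        blocks[bid][rec.d1, rec.d2] += 1
        total[rec.d1, rec.d2] += 1

    if n_records == 0:
        raise ModelError("no site records supplied")
    if total.sum() == 0:
        raise ModelError("no usable sites after filtering")
    block_list = [(bid, ConfigCounts(m=blocks[bid], m_tot=float(blocks[bid].sum())))
                  for bid in order]
    return BlockedCounts(
        blocks=block_list,
        total=ConfigCounts(m=total, m_tot=float(total.sum())),
        dropped=dict(dropped),
    )


def tally_counts(records, block_size: int = DEFAULT_BLOCK_SIZE) -> BlockedCounts:
    """Tally sorted site records into per-block configuration counts.

    ``m_tot`` counts every valid site, monomorphic included.  Invalid
    records are excluded and summarized in ``dropped`` by reason.  Records
    must be sorted by position within each chromosome.
    """
    return _tally(records, block_size, ascertain=None)


def ascertained_tally(
    records, rule: str = "any", block_size: int = DEFAULT_BLOCK_SIZE,
) -> BlockedCounts:
    """Like :func:`tally_counts` but restricted to sites whose derived
    allele is present in the outgroup (``rule="any"``: at least one copy;
    ``rule="fixed"``: both copies).  ``m_tot`` becomes the number of
    ascertained sites."""
    if rule not in ("any", "fixed"):
        raise ModelError(f"unknown ascertainment rule {rule!r}")
    return _tally(records, block_size, ascertain=rule)


def read_site_table(path) -> list[SiteRecord]:
    """Read the headered TSV site table into records."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ancestral": str})
    required = {"chrom", "pos", "ancestral", "d1", "d2"}
    missing = required - set(df.columns)
    if missing:
        raise ModelError(f"site table missing columns: {sorted(missing)}")
    has_out = "d_out" in df.columns
    records = []
    for row in df.itertuples(index=False):
        records.append(SiteRecord(
            chrom=row.chrom, pos=int(row.pos), ancestral=row.ancestral,
            d1=int(row.d1), d2=int(row.d2),
            d_out=int(row.d_out) if has_out else None,
        ))
    return records


def read_vcf_sites(path, sample1: str, sample2: str, outgroup: str | None = None,
                   aa_tag: str = "AA") -> list[SiteRecord]:
    """Minimal VCF ingestion: two sample columns plus an ancestral-allele
    INFO tag.  Sites where the ancestral allele is missing or matches
    neither REF nor ALT are marked invalid; only bi-allelic SNPs are used.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        idx = [samples.index(sample1), samples.index(sample2)]
        if outgroup is not None:
            idx.append(samples.index(outgroup))
    except ValueError as e:
        raise ModelError(f"sample not found in VCF: {e}") from e

    records = []
    for v in vcf:
        aa = v.INFO.get(aa_tag)
        invalid = None
        if not v.is_snp or len(v.ALT) != 1:
            invalid = "not_biallelic_snp"
        elif aa is None or aa.upper() in _MISSING_ALLELES:
            invalid = "missing_ancestral"
        elif aa.upper() not in (v.REF, v.ALT[0]):
            invalid = "ancestral_not_in_alleles"
        if invalid:
            records.append(SiteRecord(chrom=v.CHROM, pos=v.POS, ancestral=aa or ".",
                                      d1=0, d2=0, valid=False, reason=invalid))
            continue
        aa = aa.upper()
        gts = v.genotypes  # [allele_idx, allele_idx, phased]
        counts = []
        missing = False
        for k in idx:
            g = gts[k]
            if g[0] < 0 or g[1] < 0:
                missing = True
                break
            alleles = [v.REF if a == 0 else v.ALT[0] for a in g[:2]]
            counts.append(sum(a != aa for a in alleles))
        if missing:
            records.append(SiteRecord(chrom=v.CHROM, pos=v.POS, ancestral=aa,
                                      d1=0, d2=0, valid=False, reason="missing_genotype"))
            continue
        records.append(SiteRecord(
            chrom=v.CHROM, pos=v.POS, ancestral=aa,
            d1=counts[0], d2=counts[1],
            d_out=counts[2] if outgroup is not None else None,
        ))
    return records


def read_counts_file(path) -> ConfigCounts:
    """Read a plain ``key=value`` counts file (``m00``..``m22``, ``m_tot``)."""
    cells: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            cells[key.strip()] = float(val)
    if "m_tot" not in cells:
        raise ModelError("counts file must define m_tot")
    m_tot = cells.pop("m_tot")
    return ConfigCounts.from_cells(m_tot, **cells)


def write_counts_file(path, counts: ConfigCounts) -> None:
    with open(path, "w") as fh:
        for key, val in counts.to_dict().items():
            fh.write(f"{key}={val:.10g}\n")
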