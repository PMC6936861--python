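"""Somatic mutation catalog I/O and reference-context attachment.

Catalogs are collections of single-nucleotide substitutions keyed by sample,
loaded from MAF-dialect TSV or VCF. Each mutation can carry a fixed-width
reference context window (default 41 bases: the mutated base plus 20 flanking
bases on each side) extracted from a FASTA reference; the window is what the
downstream enrichment statistic counts motifs in.

Coordinates are 1-based inclusive throughout, as in MAF and VCF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import pysam
from pyfaidx import Fasta

VALID_BASES = frozenset("ACGT")

#: Default MAF column names (CCLE/Broad dialect); COSMIC exports load by
#: passing a column_map that renames their headers onto these.
MAF_COLUMNS = {
    "chrom": "Chromosome",
    "pos": "Start_position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "sample": "Tumor_Sample_Barcode",
}


class CatalogError(Exception):
    """Configuration or parse error while loading a catalog."""


@dataclass(frozen=True)
class Mutation:
    """A single somatic substitution.

    ``context``, when set, is an uppercase string of odd length with the
    mutated reference base at the center; positions that fall off the
    chromosome ends are padded with ``N`` so the length is always 2*flank+1.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample_id: str
    context: str | None = None

    def __post_init__(self) -> None:
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"ref/alt must be single A/C/G/T bases, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.context is not None:
            if len(self.context) % 2 != 1:
                raise ValueError("context length must be odd")
            center = self.context[len(self.context) // 2]
            if center != self.ref:
                raise ValueError(
                    f"context center {center!r} does not match ref {self.ref!r} at {self.chrom}:{self.pos}"
                )

    @property
    def trinucleotide(self) -> str | None:
        """The ref base with its immediate 5'/3' neighbours, or None if absent."""
        if self.context is None or len(self.context) < 3:
            return None
        c = len(self.context) // 2
        return self.context[c - 1 : c + 2]


@dataclass
class LoadReport:
    """Row-level accounting for a catalog load; input = loaded + skipped + duplicates."""

    n_input: int = 0
    n_loaded: int = 0
    n_skipped_non_snv: int = 0
    n_duplicates: int = 0
    n_ref_mismatch: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


class MutationCatalog:
    """Ordered per-sample lists of :class:`Mutation` with load accounting."""

    def __init__(self, mutations: Iterable[Mutation] = (), report: LoadReport | None = None):
        self._samples: dict[str, list[Mutation]] = {}
        self.report = report or LoadReport()
        seen: set[tuple[str, str, int, str]] = set()
        for m in mutations:
            key = (m.sample_id, m.chrom, m.pos, m.alt)
            if key in seen:
                self.report.n_duplicates += 1
                continue
            seen.add(key)
            self._samples.setdefault(m.sample_id, []).append(m)

    def __len__(self) -> int:
        return sum(len(v) for v in self._samples.values())

    def __iter__(self) -> Iterator[Mutation]:
        for muts in self._samples.values():
            yield from muts

    @property
    def samples(self) -> list[str]:
        return list(self._samples)

    def mutations_for(self, sample_id: str) -> list[Mutation]:
        return list(self._samples.get(sample_id, []))

    def items(self) -> Iterator[tuple[str, list[Mutation]]]:
        for sid, muts in self._samples.items():
            yield sid, list(muts)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (m.sample_id, m.chrom, m.pos, m.ref, m.alt, m.context or "")
            for m in self
        ]
        return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref", "alt", "context"])


class ReferenceSequence:
    """Mapping of chromosome name to uppercase sequence with N-padded slicing."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}
        for name, seq in self._seqs.items():
            extra = set(seq) - set("ACGTN")
            if extra:
                raise ValueError(f"sequence {name} contains invalid characters {sorted(extra)}")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceSequence":
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: fa[name][:] for name in fa.keys()})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def keys(self):
        return self._seqs.keys()

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return [start, end] 1-based inclusive, N-padded beyond the ends."""
        seq = self._seqs[chrom]
        left_pad = max(0, 1 - start)
        right_pad = max(0, end - len(seq))
        core = seq[max(start - 1, 0) : min(end, len(seq))]
        return "N" * left_pad + core + "N" * right_pad

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref in VALID_BASES and alt in VALID_BASES and ref != alt


def read_maf_catalog(path: str | Path, column_map: Mapping[str, str] | None = None) -> MutationCatalog:
    """Load a MAF-dialect TSV, keeping only single-nucleotide substitutions.

    Parameters
    ----------
    path:
        Tab-delimited file with a header row. Only five columns are required
        (chromosome, 1-based start, reference allele, tumor allele, sample
        barcode); everything else is ignored.
    column_map:
        Optional ``{role: actual_header}`` overrides for any of the roles
        ``chrom, pos, ref, alt, sample``, so differently headed exports load
        without editing the file.
    """
    names = dict(MAF_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(names)
        if unknown:
            raise CatalogError(f"unknown column_map roles: {sorted(unknown)}")
        names.update(column_map)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty file, returning empty catalog")
        return MutationCatalog()
    missing = [col for col in names.values() if col not in df.columns]
    if missing:
        raise CatalogError(f"required column(s) missing from {path}: {missing}")

    report = LoadReport(n_input=len(df))
    muts: list[Mutation] = []
    # Column access via the frame keeps arbitrary header names intact.
    chrom_s = df[names["chrom"]].astype(str)
    pos_s = df[names["pos"]]
    ref_s = df[names["ref"]].astype(str).str.upper()
    alt_s = df[names["alt"]].astype(str).str.upper()
    sample_s = df[names["sample"]].astype(str)
    for chrom, pos, ref, alt, sample in zip(chrom_s, pos_s, ref_s, alt_s, sample_s):
        if not _is_snv(ref, alt):
            report.n_skipped_non_snv += 1
            continue
        muts.append(Mutation(chrom=chrom, pos=int(pos), ref=ref, alt=alt, sample_id=sample))
    catalog = MutationCatalog(muts, report)
    catalog.report.n_loaded = len(catalog)
    if catalog.report.n_duplicates:
        warnings.warn(f"{path}: dropped {catalog.report.n_duplicates} exact duplicate record(s)")
    return catalog


def read_vcf_catalog(
    path: str | Path,
    sample_source: str = "column",
    fixed_label: str = "sample",
) -> MutationCatalog:
    """Load SNVs from a VCF 4.x file.

    With ``sample_source="column"`` one Mutation is emitted per ALT per
    genotype column carrying that ALT; with ``"fixed_label"`` every record is
    attributed to ``fixed_label`` (for single-sample, genotype-less VCFs).
    Multi-allelic records are split; non-SNV ALTs (indels, symbolic) skipped.
    """
    if sample_source not in ("column", "fixed_label"):
        raise CatalogError(f"sample_source must be 'column' or 'fixed_label', got {sample_source!r}")
    report = LoadReport()
    muts: list[Mutation] = []
    with pysam.VariantFile(str(path)) as vf:
        vcf_samples = list(vf.header.samples)
        if sample_source == "column" and not vcf_samples:
            raise CatalogError(f"{path}: sample_source='column' but the VCF has no genotype columns")
        for rec in vf:
            for alt_i, alt in enumerate(rec.alts or (), start=1):
                report.n_input += 1
                ref = (rec.ref or "").upper()
                alt = (alt or "").upper()
                if not _is_snv(ref, alt):
                    report.n_skipped_non_snv += 1
                    continue
                if sample_source == "fixed_label":
                    carriers = [fixed_label]
                else:
                    carriers = [
                        s for s in vcf_samples
                        if alt_i in (rec.samples[s].get("GT") or ())
                    ]
                for sid in carriers:
                    muts.append(Mutation(chrom=rec.chrom, pos=rec.pos, ref=ref, alt=alt, sample_id=sid))
    catalog = MutationCatalog(muts, report)
    catalog.report.n_loaded = len(catalog)
    return catalog


def attach_contexts(
    catalog: MutationCatalog, reference: ReferenceSequence, flank: int = 20
) -> MutationCatalog:
    """Attach a (2*flank+1)-base reference window centered on each mutation.

    Mutations whose stated reference base disagrees with the reference
    sequence are excluded and counted in the returned catalog's report
    (``n_ref_mismatch``). Idempotent: re-attaching with the same reference
    and flank reproduces the same contexts.
    """
    missing = sorted({m.chrom for m in catalog if m.chrom not in reference})
    if missing:
        raise CatalogError(f"chromosome(s) absent from reference: {missing}")
    report = LoadReport(**catalog.report.as_dict())
    out: list[Mutation] = []
    for m in catalog:
        if reference.base(m.chrom, m.pos) != m.ref:
            report.n_ref_mismatch += 1
            continue
        ctx = reference.fetch(m.chrom, m.pos - flank, m.pos + flank)
        out.append(replace(m, context=ctx))
    report.n_loaded = len(out)
    return MutationCatalog(out, report)


def write_catalog_tsv(catalog: MutationCatalog, path: str | Path) -> None:
    """Write the canonical catalog TSV (sample_id, chrom, pos, ref, alt, context)."""
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path: str | Path) -> MutationCatalog:
    """Read a canonical catalog TSV written by :func:`write_catalog_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str}, keep_default_na=False)
    muts = [
        Mutation(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            sample_id=str(r.sample_id),
            context=(str(r.context) or None) if "context" in df.columns else None,
        )
        for r in df.itertuples(index=False)
    ]
    cat = MutationCatalog(muts)
    cat.report.n_input = len(df)
    cat.report.n_loaded = len(cat)
    return cat


def write_load_report(report: LoadReport, path: str | Path) -> None:
    pd.DataFrame([report.as_dict()]).to_csv(path, sep="\t", index=False)
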