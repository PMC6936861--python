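"""Synthetic data generators with planted truth.

Every input the pipeline consumes can be generated here with known ground
truth, so each stage is testable end-to-end without external cohorts:

* mutation catalogs on a context-rich reference, with a controllable
  fraction of true APOBEC events planted at TCW centers (the remainder drawn
  from a background substitution spectrum at compatible sites);
* paralog transcript pairs built from a shared high-identity core flanked
  by independent unique segments, mirroring the APOBEC3A/APOBEC3B
  architecture (a ~90%-identical core with unique 5'/3' ends);
* aligned-read streams from those transcripts, emitted directly as
  alignment records (full-match CIGARs, optional substitution errors) so no
  external aligner is needed;
* expression-mutation cohorts with a known log-linear link between one
  gene's expression and the mutation load of signature-positive samples.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog_io import Mutation, MutationCatalog, ReferenceSequence, attach_contexts
from .paralog import AlignedReadRecord, TranscriptPair, UniqueRegionSet

BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the 12 substitution types, for background spectra
SUBSTITUTION_TYPES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)


def scan_tcw_sites(seq: str) -> list[int]:
    """1-based positions whose center base is a TCW target on either strand.

    Plus-strand TCA/TCT (center C) and their reverse complements TGA/AGA
    (center G) are both reported.
    """
    sites = []
    for i in range(1, len(seq) - 1):
        tri = seq[i - 1 : i + 2]
        if tri in ("TCA", "TCT", "TGA", "AGA"):
            sites.append(i + 1)
    return sites


# ---------------------------------------------------------------------------
# mutation catalogs


@dataclass
class CatalogSimConfig:
    """Conditions for one simulated sample's mutation catalog.

    ``apobec_fraction`` is the fraction of mutations planted as true APOBEC
    events (C>T/C>G at TCW, split between the two alternates by
    ``ct_vs_cg_split``); the rest are background substitutions drawn from
    ``background_spectrum`` (uniform over the 12 types by default) at
    uniformly chosen compatible positions, so some land in TCW by chance —
    exactly the null the enrichment test must absorb.
    """

    reference_length: int = 20_000
    tcw_density_target: float = 0.0625  # the uniform-sequence expectation
    n_mutations: int = 500
    apobec_fraction: float = 0.0
    ct_vs_cg_split: float = 0.5
    background_spectrum: dict[str, float] | None = None
    seed: int = 0
    sample_id: str = "S1"
    chrom: str = "chrSim"

    def __post_init__(self):
        if self.n_mutations < 0:
            raise ValueError("n_mutations must be >= 0")
        if not 0.0 <= self.apobec_fraction <= 1.0:
            raise ValueError("apobec_fraction must be in [0, 1]")
        if self.background_spectrum is not None:
            total = sum(self.background_spectrum.values())
            if not math.isclose(total, 1.0, rel_tol=1e-9):
                raise ValueError("background_spectrum probabilities must sum to 1")


def simulate_reference(config: CatalogSimConfig) -> tuple[ReferenceSequence, list[int]]:
    """Random reference whose TCW density is near the target, plus its sites.

    Starts from an iid-uniform sequence (natural TCW density 1/16) and
    plants or destroys motifs until the realized density is within 20%
    (relative) of the target. The returned site list is an exact scan of the
    emitted sequence.
    """
    L = config.reference_length
    if L < 1000:
        raise ValueError("reference_length must be >= 1000")
    target = config.tcw_density_target
    if target < 0.005 or target > 0.3:
        raise ValueError(f"tcw_density_target {target} unattainable (supported range 0.005-0.3)")
    rng = np.random.default_rng(config.seed)
    seq = list(rng.choice(BASES, size=L))
    motifs = ("TCA", "TCT", "TGA", "AGA")
    for _ in range(200):
        sites = scan_tcw_sites("".join(seq))
        density = len(sites) / L
        if abs(density - target) <= 0.2 * target:
            break
        deficit = int(round((target - density) * L))
        if deficit > 0:
            starts = rng.integers(1, L - 2, size=max(deficit, 1))
            for s in starts:
                seq[s - 1 : s + 2] = list(motifs[rng.integers(len(motifs))])
        else:
            kill = rng.choice(len(sites), size=min(-deficit, len(sites)), replace=False)
            for k in kill:
                center = sites[k] - 1
                seq[center] = "A" if seq[center] != "A" else "G"
    else:
        raise ValueError("could not reach the requested TCW density")
    final = "".join(seq)
    return ReferenceSequence({config.chrom: final}), scan_tcw_sites(final)


def simulate_catalog(
    reference: ReferenceSequence,
    tcw_sites: Sequence[int],
    config: CatalogSimConfig,
    flank: int = 20,
) -> tuple[MutationCatalog, int]:
    """One sample's catalog with planted APOBEC events; returns its truth count.

    Exactly ``round(apobec_fraction * n_mutations)`` mutations are placed at
    distinct TCW centers with the signature-consistent alternate; the rest
    are background substitutions at distinct compatible positions. Contexts
    are attached from the reference before returning.
    """
    rng = np.random.default_rng(config.seed)
    chrom = config.chrom
    seq = reference[chrom]
    n_ap = int(round(config.apobec_fraction * config.n_mutations))
    if n_ap > len(tcw_sites):
        raise ValueError(f"only {len(tcw_sites)} TCW sites for {n_ap} planted events")
    used: set[int] = set()
    muts: list[Mutation] = []

    chosen = rng.choice(len(tcw_sites), size=n_ap, replace=False)
    for idx in chosen:
        pos = int(tcw_sites[idx])
        used.add(pos)
        ref = seq[pos - 1]
        ct = rng.random() < config.ct_vs_cg_split
        if ref == "C":
            alt = "T" if ct else "G"
        else:  # center G: complementary strand event
            alt = "A" if ct else "C"
        muts.append(Mutation(chrom=chrom, pos=pos, ref=ref, alt=alt, sample_id=config.sample_id))

    spectrum = config.background_spectrum or {t: 1 / 12 for t in SUBSTITUTION_TYPES}
    types = list(spectrum)
    probs = np.array([spectrum[t] for t in types])
    pos_by_base = {b: np.flatnonzero(np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)) + 1 for b in "ACGT"}
    n_bg = config.n_mutations - n_ap
    drawn_types = rng.choice(len(types), size=n_bg, p=probs)
    for ti in drawn_types:
        ref, alt = types[ti].split(">")
        candidates = pos_by_base[ref]
        for _ in range(1000):
            pos = int(candidates[rng.integers(len(candidates))])
            if pos not in used:
                used.add(pos)
                break
        else:
            raise ValueError(f"could not place a background {ref}>{alt} mutation")
        muts.append(Mutation(chrom=chrom, pos=pos, ref=ref, alt=alt, sample_id=config.sample_id))

    catalog = attach_contexts(MutationCatalog(muts), reference, flank=flank)
    return catalog, n_ap


def simulate_catalog_cohort(
    reference: ReferenceSequence,
    tcw_sites: Sequence[int],
    base_config: CatalogSimConfig,
    n_samples: int,
    seed: int = 0,
) -> tuple[MutationCatalog, dict[str, int]]:
    """A multi-sample catalog: independent samples under the same conditions."""
    from dataclasses import replace as dc_replace

    rng = np.random.default_rng(seed)
    all_muts: list[Mutation] = []
    truth: dict[str, int] = {}
    for i in range(n_samples):
        cfg = dc_replace(base_config, seed=int(rng.integers(2**31)), sample_id=f"S{i+1:03d}")
        cat, n_ap = simulate_catalog(reference, tcw_sites, cfg)
        truth[cfg.sample_id] = n_ap
        all_muts.extend(cat)
    return MutationCatalog(all_muts), truth


# ---------------------------------------------------------------------------
# paralog transcript pairs and reads


@dataclass
class ReadSimConfig:
    """Architecture of a simulated paralog pair and its read libraries.

    Defaults mirror the APOBEC3A/APOBEC3B situation: a shared core at 93%
    identity, a 350-nt unique 5' segment on transcript A, and 622/190-nt
    unique 5'/3' segments on transcript B; 101-nt reads.
    """

    core_length: int = 1000
    core_identity: float = 0.93
    unique_a: tuple[int, int] = (350, 150)  # 5', 3' unique segment lengths
    unique_b: tuple[int, int] = (622, 190)
    abundances: tuple[int, int] = (1000, 1000)  # reads from A, B
    read_length: int = 101
    error_rate: float = 0.0
    seed: int = 0
    name_a: str = "paralogA"
    name_b: str = "paralogB"

    def __post_init__(self):
        if not 0.8 < self.core_identity <= 1.0:
            raise ValueError("core_identity must be in (0.8, 1.0]")
        if min(self.abundances) < 0:
            raise ValueError("abundances must be >= 0")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def simulate_paralog_pair(config: ReadSimConfig) -> tuple[TranscriptPair, UniqueRegionSet]:
    """Two transcripts sharing a mutated copy of one core, plus truth regions."""
    rng = np.random.default_rng(config.seed)
    core_a = _random_seq(rng, config.core_length)
    core_b = list(core_a)
    n_sub = int(round((1.0 - config.core_identity) * config.core_length))
    for i in rng.choice(config.core_length, size=n_sub, replace=False):
        others = [b for b in "ACGT" if b != core_b[i]]
        core_b[i] = others[rng.integers(3)]
    a5, a3 = config.unique_a
    b5, b3 = config.unique_b
    seq_a = _random_seq(rng, a5) + core_a + _random_seq(rng, a3)
    seq_b = _random_seq(rng, b5) + "".join(core_b) + _random_seq(rng, b3)
    if config.read_length > min(len(seq_a), len(seq_b)):
        raise ValueError("read_length exceeds a transcript length")

    regions: dict[str, list[tuple[int, int]]] = {config.name_a: [], config.name_b: []}
    if a5:
        regions[config.name_a].append((1, a5))
    if a3:
        regions[config.name_a].append((a5 + config.core_length + 1, len(seq_a)))
    if b5:
        regions[config.name_b].append((1, b5))
    if b3:
        regions[config.name_b].append((b5 + config.core_length + 1, len(seq_b)))
    pair = TranscriptPair(name_a=config.name_a, seq_a=seq_a, name_b=config.name_b, seq_b=seq_b)
    return pair, UniqueRegionSet(regions=regions)


@dataclass
class SimulatedRead:
    record: AlignedReadRecord
    sequence: str
    origin: str
    origin_interval: tuple[int, int]
    is_core: bool
    is_ambiguous: bool


def simulate_reads(
    pair: TranscriptPair,
    config: ReadSimConfig,
    restrict: str | None = None,
) -> list[SimulatedRead]:
    """Uniform-start reads from each transcript with full-match CIGARs.

    ``restrict="core"`` confines start positions to the shared core (useful
    for cross-assignment checks); ``restrict="unique"`` confines them to the
    unique segments. Substitution errors at ``error_rate`` leave the CIGAR
    M-only, as real mismatches do. A read whose (possibly erroneous)
    sequence occurs exactly in both transcripts is flagged ambiguous.
    """
    rng = np.random.default_rng(config.seed + 1)
    rl = config.read_length
    core_span = {
        pair.name_a: (config.unique_a[0] + 1, config.unique_a[0] + config.core_length),
        pair.name_b: (config.unique_b[0] + 1, config.unique_b[0] + config.core_length),
    }
    out: list[SimulatedRead] = []
    for (name, seq), n_reads in zip(
        ((pair.name_a, pair.seq_a), (pair.name_b, pair.seq_b)), config.abundances
    ):
        if rl > len(seq):
            raise ValueError(f"read_length {rl} exceeds transcript {name} length {len(seq)}")
        cs, ce = core_span[name]
        if restrict == "core":
            lo, hi = cs, ce - rl + 1
        elif restrict == "unique":
            lo, hi = 1, len(seq) - rl + 1  # filtered below
        elif restrict is None:
            lo, hi = 1, len(seq) - rl + 1
        else:
            raise ValueError(f"unknown restrict {restrict!r}")
        if hi < lo:
            raise ValueError("restricted region shorter than the read length")
        i = 0
        attempts = 0
        while i < n_reads:
            attempts += 1
            if attempts > 100 * max(n_reads, 1):
                raise ValueError("could not place reads under the requested restriction")
            start = int(rng.integers(lo, hi + 1))
            end = start + rl - 1
            if restrict == "unique" and not (end < cs or start > ce):
                continue
            read_seq = list(seq[start - 1 : end])
            if config.error_rate > 0:
                errs = np.flatnonzero(rng.random(rl) < config.error_rate)
                for e in errs:
                    others = [b for b in "ACGT" if b != read_seq[e]]
                    read_seq[e] = others[rng.integers(3)]
            read_str = "".join(read_seq)
            other_seq = pair.seq_b if name == pair.name_a else pair.seq_a
            rec = AlignedReadRecord(
                name=f"{name}_r{i:06d}",
                target=name,
                start=start,
                cigar=((rl, "M"),),
                read_length=rl,
            )
            out.append(
                SimulatedRead(
                    record=rec,
                    sequence=read_str,
                    origin=name,
                    origin_interval=(start, end),
                    is_core=not (end < cs or start > ce),
                    is_ambiguous=read_str in other_seq,
                )
            )
            i += 1
    return out


def write_sam(pair: TranscriptPair, reads: Iterable[SimulatedRead], path: str | Path) -> None:
    """Write simulated reads as a plain-text SAM against the two transcripts."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{pair.name_a}\tLN:{len(pair.seq_a)}\n")
        fh.write(f"@SQ\tSN:{pair.name_b}\tLN:{len(pair.seq_b)}\n")
        for r in reads:
            cig = "".join(f"{n}{op}" for n, op in r.record.cigar)
            fh.write(
                f"{r.record.name}\t0\t{r.record.target}\t{r.record.start}\t60\t"
                f"{cig}\t*\t0\t0\t{r.sequence}\t{'I' * len(r.sequence)}\n"
            )


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[SimulatedRead], path: str | Path) -> None:
    """Optional FASTQ export for end-to-end runs with a real aligner."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.record.name}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


# ---------------------------------------------------------------------------
# expression-mutation cohorts


@dataclass
class CohortSimConfig:
    """A cohort with a known link between expression and mutation load.

    Expression per gene is log-normal (natural-log mean/sd). For samples
    flagged APOBEC-mutated (a ``mutated_fraction`` of the cohort), the
    mutation load follows ``round(exp(intercept + slope*ln(x) + eps))`` with
    ``eps ~ N(0, noise_sd)`` and x the link gene's expression; unflagged
    samples have a minimum estimate of zero, as the enrichment statistic
    defines. Defaults emulate a cell-line panel: 28 samples, half mutated,
    and a log-scale generating correlation near 0.6.
    """

    n_samples: int = 28
    gene_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"A3A": (0.0, 1.0), "A3B": (1.5, 0.8)}
    )
    link_gene: str = "A3A"
    intercept: float = 4.0
    slope: float = 1.0
    noise_sd: float = 1.33
    mutated_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if self.noise_sd <= 0 or any(sd <= 0 for _, sd in self.gene_params.values()):
            raise ValueError("standard deviations must be positive")

    @property
    def generating_r(self) -> float:
        """Theoretical log-scale Pearson correlation among mutated samples."""
        sd_x = self.gene_params[self.link_gene][1]
        return self.slope * sd_x / math.hypot(self.slope * sd_x, self.noise_sd)


def simulate_cohort(config: CohortSimConfig) -> tuple[pd.DataFrame, dict[str, float]]:
    """Sample a cohort table; returns (table, generating parameters)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    table = pd.DataFrame({"sample_id": [f"S{i+1:03d}" for i in range(n)]})
    for gene, (mu, sd) in config.gene_params.items():
        table[gene] = np.exp(rng.normal(mu, sd, size=n))
    n_mut = int(round(config.mutated_fraction * n))
    flags = np.zeros(n, dtype=bool)
    flags[rng.choice(n, size=n_mut, replace=False)] = True
    table["is_apobec_mutated"] = flags
    x = table[config.link_gene].to_numpy()
    eps = rng.normal(0.0, config.noise_sd, size=n)
    load = np.round(np.exp(config.intercept + config.slope * np.log(x) + eps))
    table["min_estimate"] = np.where(flags, load, 0.0)
    params = {
        "generating_r": config.generating_r,
        "slope": config.slope,
        "noise_sd": config.noise_sd,
        "n_mutated": float(n_mut),
    }
    return table, params
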