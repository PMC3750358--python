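"""Ground-truthed synthetic multiplexed amplicon runs.

Emulates a pooled two-gene pyrosequencing experiment over bulk larval
samples: per-site communities of known composition, fusion-primer read
structure (MID tag + universal tail + template primer + insert), dual-MID
mis-tagging at a configurable rate, per-specimen amplification bias,
substitution errors and homopolymer ±1 indels. Every emitted read carries
full provenance so downstream demultiplexing, identification and
detection can be validated read-by-read.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .refdb import (
    DEFAULT_PRIMER_SETS,
    GENES,
    TAIL1,
    TAIL2,
    PrimerSet,
    ReferenceDB,
    SpeciesRecord,
)
from .sequtil import IUPAC_SETS, revcomp

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimParams:
    """Error and yield structure of a simulated run.

    Defaults reflect a high-quality amplicon run: a mis-tag (tag-jump)
    rate of 8%, and per-read error rates low enough that nearly all reads
    stay above 98% identity to their source haplotype.
    """

    substitution_rate: float = 0.004
    homopolymer_indel_rate: float = 0.002
    mid_mistag_rate: float = 0.08
    reads_per_individual_mean: float = 15.0
    amplification_dispersion: float = 0.6
    gene_failure: Mapping[str, Mapping[str, float]] | None = None
    n_runs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "homopolymer_indel_rate", "mid_mistag_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.reads_per_individual_mean <= 0:
            raise ValueError("reads_per_individual_mean must be > 0")
        if self.amplification_dispersion < 0:
            raise ValueError("amplification_dispersion must be >= 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    def gene_success(self, species: str, gene: str) -> float:
        if self.gene_failure is None:
            return 1.0
        return float(self.gene_failure.get(species, {}).get(gene, 1.0))


@dataclass(frozen=True)
class MidScheme:
    """Per-sample (forward MID, reverse MID) tag pairs plus universal tails."""

    samples: dict[str, tuple[str, str]]
    tail1: str = TAIL1
    tail2: str = TAIL2

    def __post_init__(self) -> None:
        pairs = list(self.samples.values())
        if len(set(pairs)) != len(pairs):
            raise ValueError("MID pairs must be unique per sample")
        lengths = {len(m) for p in pairs for m in p}
        if len(lengths) > 1:
            raise ValueError("all MIDs must have the same length")

    @property
    def mid_length(self) -> int:
        return len(next(iter(self.samples.values()))[0])

    @property
    def forward_mids(self) -> set[str]:
        return {f for f, _ in self.samples.values()}

    @property
    def reverse_mids(self) -> set[str]:
        return {r for _, r in self.samples.values()}

    def sample_of(self, fwd: str, rev: str) -> str | None:
        for sample, pair in self.samples.items():
            if pair == (fwd, rev):
                return sample
        return None

    def to_tsv(self, path) -> None:
        rows = [{"sample": s, "fwd_mid": f, "rev_mid": r} for s, (f, r) in self.samples.items()]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MidScheme":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls({row["sample"]: (row.fwd_mid, row.rev_mid) for _, row in df.iterrows()})


def make_mid_scheme(
    sample_ids: Sequence[str], seed: int = 0, length: int = 10, min_distance: int = 3
) -> MidScheme:
    """Generate Roche-style 10-base MID tags with pairwise Hamming distance ≥3.

    Tags are drawn greedily at random (seeded); forward and reverse tags
    come from the same pool, one distinct tag per role per sample.
    """
    rng = np.random.default_rng(seed)
    needed = 2 * len(sample_ids)
    tags: list[str] = []
    attempts = 0
    while len(tags) < needed:
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not build MID pool; relax constraints")
        cand = "".join(rng.choice(_BASES, size=length))
        if len(set(cand)) < 2:  # avoid pure homopolymer tags
            continue
        if all(sum(a != b for a, b in zip(cand, t)) >= min_distance for t in tags):
            tags.append(cand)
    samples = {
        sid: (tags[2 * i], tags[2 * i + 1]) for i, sid in enumerate(sample_ids)
    }
    return MidScheme(samples)


@dataclass(frozen=True)
class Specimen:
    specimen_id: str
    site: str
    species: str
    haplotypes: Mapping[str, str]  # gene -> amplicon insert


@dataclass(frozen=True)
class ReadProvenance:
    read_id: str
    site: str
    specimen_id: str
    species: str
    gene: str
    run: str
    direction: str  # forward | reverse
    n_subst: int
    n_indel: int
    mistagged: bool
    fwd_mid: str
    rev_mid: str


@dataclass
class SimTruth:
    """Ground truth: the community plus per-read provenance."""

    site_spec: dict[str, dict[str, int]]
    community: list[Specimen]
    reads: list[ReadProvenance] = field(default_factory=list)

    def community_frame(self) -> pd.DataFrame:
        rows = [
            {"site": site, "species": sp, "n_individuals": n}
            for site, spec in self.site_spec.items()
            for sp, n in spec.items()
        ]
        return pd.DataFrame(rows, columns=["site", "species", "n_individuals"])

    _READ_COLUMNS = (
        "read_id", "site", "specimen_id", "species", "gene", "run",
        "direction", "n_subst", "n_indel", "mistagged", "fwd_mid", "rev_mid",
    )

    def reads_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [vars(r) for r in self.reads], columns=list(self._READ_COLUMNS)
        )


def _concrete(primer: str, rng: np.random.Generator) -> str:
    """Instantiate a degenerate primer: pick one base per IUPAC code."""
    return "".join(
        c if c in "ACGT" else sorted(IUPAC_SETS[c])[rng.integers(len(IUPAC_SETS[c]))]
        for c in primer
    )


def simulate_community(
    db: ReferenceDB,
    site_spec: Mapping[str, Mapping[str, int]],
    seed: int = 0,
) -> SimTruth:
    """Lay out specimens per site; each gets a reference haplotype per gene.

    ``site_spec`` maps site → species → number of individuals. Haplotypes
    are resampled with replacement from the species' records in ``db``
    (amplicon-region sequences). Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    community: list[Specimen] = []
    counter = itertools.count(1)
    for site in site_spec:
        for species in site_spec[site]:
            n = site_spec[site][species]
            if species not in db.species_index:
                raise ValueError(f"species {species!r} not in reference DB")
            if n < 0:
                raise ValueError("individual counts must be >= 0")
            for _ in range(n):
                haps = {}
                for gene in GENES:
                    recs = db.records_for(species, gene)
                    if recs:
                        haps[gene] = recs[rng.integers(len(recs))].sequence
                if not haps:
                    raise ValueError(f"species {species!r} has no records for any gene")
                community.append(
                    Specimen(f"sp{next(counter):05d}", site, species, haps)
                )
    return SimTruth(
        site_spec={s: dict(v) for s, v in site_spec.items()}, community=community
    )


def _apply_errors(
    insert: str, params: SimParams, rng: np.random.Generator
) -> tuple[str, int, int]:
    """Substitutions then homopolymer ±1 indels; returns (seq, n_subst, n_indel)."""
    seq = list(insert)
    n_subst = 0
    if params.substitution_rate > 0:
        hits = np.nonzero(rng.random(len(seq)) < params.substitution_rate)[0]
        for i in hits:
            alternatives = [b for b in "ACGT" if b != seq[i]]
            seq[i] = alternatives[rng.integers(3)]
            n_subst += 1
    n_indel = 0
    if params.homopolymer_indel_rate > 0:
        out: list[str] = []
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            run = seq[i:j]
            if j - i >= 3 and rng.random() < params.homopolymer_indel_rate:
                if rng.random() < 0.5:
                    run = run + [seq[i]]
                else:
                    run = run[:-1]
                n_indel += 1
            out.extend(run)
            i = j
        seq = out
    return "".join(seq), n_subst, n_indel


def simulate_reads(
    truth: SimTruth,
    params: SimParams,
    mids: MidScheme,
    primer_sets: Iterable[PrimerSet] = DEFAULT_PRIMER_SETS,
) -> tuple[list[tuple[str, str]], SimTruth]:
    """Emit tagged, error-bearing reads for a community; completes the truth.

    A read in reference orientation is
    ``fwd_MID + tail1 + fwd_primer + insert + rc(rev_primer) + rc(tail2) + rc(rev_MID)``;
    reverse-direction reads are emitted as the reverse complement of that
    construct. Expected reads per specimen per gene per run =
    ``reads_per_individual_mean`` × the specimen's lognormal amplification
    factor, thinned by any species×gene amplification-failure probability.
    Mis-tagged reads have their MID pair redrawn from tags in use and are
    flagged in the truth table whenever the emitted pair differs from the
    sample's own pair.

    Sites must appear in the MID scheme as samples. Returns
    ``(reads, truth)`` where reads are ``(read_id, sequence)`` pairs.
    """
    rng = np.random.default_rng(params.seed)
    primer_by_gene = {p.gene: p for p in primer_sets}
    missing = [s for s in truth.site_spec if s not in mids.samples]
    if missing:
        raise ValueError(f"sites without MID pairs: {missing}")
    fwd_pool = sorted(mids.forward_mids)
    rev_pool = sorted(mids.reverse_mids)

    amp_factor = {
        sp.specimen_id: float(np.exp(rng.normal(0.0, params.amplification_dispersion)))
        if params.amplification_dispersion > 0
        else 1.0
        for sp in truth.community
    }
    runs = [f"run{k + 1}" for k in range(params.n_runs)]
    # species×gene×run amplification success (primer failure hits a whole pool)
    success: dict[tuple[str, str, str], bool] = {}
    for run in runs:
        for sp in sorted({(s.species) for s in truth.community}):
            for gene in GENES:
                p = params.gene_success(sp, gene)
                success[(sp, gene, run)] = bool(rng.random() < p) if p < 1.0 else True

    reads: list[tuple[str, str]] = []
    provenance: list[ReadProvenance] = []
    serial = itertools.count(1)
    for specimen in truth.community:
        own_fwd, own_rev = mids.samples[specimen.site]
        for run in runs:
            for gene, insert in specimen.haplotypes.items():
                if not success[(specimen.species, gene, run)]:
                    continue
                lam = params.reads_per_individual_mean * amp_factor[specimen.specimen_id]
                n_reads = int(rng.poisson(lam))
                primers = primer_by_gene[gene]
                for _ in range(n_reads):
                    errored, n_subst, n_indel = _apply_errors(insert, params, rng)
                    fwd_mid, rev_mid = own_fwd, own_rev
                    if params.mid_mistag_rate > 0 and rng.random() < params.mid_mistag_rate:
                        fwd_mid = fwd_pool[rng.integers(len(fwd_pool))]
                        rev_mid = rev_pool[rng.integers(len(rev_pool))]
                    mistagged = (fwd_mid, rev_mid) != (own_fwd, own_rev)
                    construct = (
                        fwd_mid
                        + mids.tail1
                        + _concrete(primers.fwd, rng)
                        + errored
                        + revcomp(_concrete(primers.rev, rng))
                        + revcomp(mids.tail2)
                        + revcomp(rev_mid)
                    )
                    direction = "forward" if rng.random() < 0.5 else "reverse"
                    seq = construct if direction == "forward" else revcomp(construct)
                    read_id = f"{run}_{next(serial):07d}"
                    reads.append((read_id, seq))
                    provenance.append(
                        ReadProvenance(
                            read_id=read_id,
                            site=specimen.site,
                            specimen_id=specimen.specimen_id,
                            species=specimen.species,
                            gene=gene,
                            run=run,
                            direction=direction,
                            n_subst=n_subst,
                            n_indel=n_indel,
                            mistagged=mistagged,
                            fwd_mid=fwd_mid,
                            rev_mid=rev_mid,
                        )
                    )
    completed = SimTruth(truth.site_spec, truth.community, provenance)
    return reads, completed


def simulate_reference_db(
    n_species: int = 20,
    n_per_species: int = 3,
    intra_divergence: float = 0.02,
    inter_divergence: float = 0.12,
    primer_sets: Iterable[PrimerSet] = DEFAULT_PRIMER_SETS,
    seed: int = 0,
    with_primer_flanks: bool = False,
) -> ReferenceDB:
    """Synthetic two-gene reference library with a programmed barcode gap.

    Species sit on a star phylogeny: each species centroid evolves from a
    shared ancestor along a branch of ``inter_divergence/2`` expected
    substitutions per site, and each specimen from its centroid along an
    ``intra_divergence/2`` branch. Substitution counts per site are
    Poisson (multiple hits allowed) with uniform choice among the three
    alternative bases, so the distance *estimated* between two tips by a
    multiple-hit-correcting model matches the programmed divergence in
    expectation. With ``with_primer_flanks`` the records are full-length
    (primer sites included) so amplicon extraction can be exercised;
    otherwise they are amplicon-region sequences.
    """
    rng = np.random.default_rng(seed)
    db = ReferenceDB()

    def mutate(seq: np.ndarray, branch_length: float) -> np.ndarray:
        out = seq.copy()
        n_events = rng.poisson(branch_length, size=len(seq))
        for i in np.nonzero(n_events)[0]:
            for _ in range(int(n_events[i])):
                choices = [b for b in "ACGT" if b != out[i]]
                out[i] = choices[rng.integers(3)]
        return out

    species_names = [f"Simulomyia sp.{i + 1}" for i in range(n_species)]
    for primers in primer_sets:
        length = primers.expected_amplicon_length
        ancestor = rng.choice(_BASES, size=length)
        for si, species in enumerate(species_names):
            centroid = mutate(ancestor, inter_divergence / 2.0)
            for k in range(n_per_species):
                hap = mutate(centroid, intra_divergence / 2.0)
                insert = "".join(hap)
                if with_primer_flanks:
                    seq = (
                        _concrete(primers.fwd, rng)
                        + insert
                        + revcomp(_concrete(primers.rev, rng))
                    )
                else:
                    seq = insert
                db.add(
                    SpeciesRecord(
                        specimen_id=f"S{si + 1:03d}-{k + 1}",
                        species=species,
                        gene=primers.gene,
                        sequence=seq,
                        source="simulated",
                    )
                )
    return db


# ---------------------------------------------------------------------------
# run IO

def write_run(
    reads: Sequence[tuple[str, str]],
    truth: SimTruth,
    outdir: str | Path,
    fastq: bool = False,
) -> dict[str, Path]:
    """Write a simulated run: reads.fasta (+ optional flat-quality FASTQ),
    per-read truth TSV and community TSV. Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    records = [SeqRecord(Seq(s), id=rid, description="") for rid, s in reads]
    paths["reads_fasta"] = outdir / "reads.fasta"
    SeqIO.write(records, str(paths["reads_fasta"]), "fasta")
    if fastq:
        for rec in records:
            rec.letter_annotations["phred_quality"] = [30] * len(rec.seq)
        paths["reads_fastq"] = outdir / "reads.fastq"
        SeqIO.write(records, str(paths["reads_fastq"]), "fastq")
    paths["truth_reads"] = outdir / "truth_reads.tsv"
    truth.reads_frame().to_csv(paths["truth_reads"], sep="\t", index=False)
    paths["community"] = outdir / "community.tsv"
    truth.community_frame().to_csv(paths["community"], sep="\t", index=False)
    return paths


def read_run(outdir: str | Path) -> tuple[list[tuple[str, str]], pd.DataFrame, pd.DataFrame]:
    """Read back a written run: (reads, truth_reads frame, community frame)."""
    outdir = Path(outdir)
    reads = [
        (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(outdir / "reads.fasta"), "fasta")
    ]
    truth = pd.read_csv(outdir / "truth_reads.tsv", sep="\t")
    community = pd.read_csv(outdir / "community.tsv", sep="\t")
    return reads, truth, community
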