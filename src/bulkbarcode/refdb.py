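"""Reference barcode library: loading, validation, indexing, amplicon extraction.

The reference database holds Sanger-quality voucher sequences for two
mitochondrial markers (COI and CytB). Species identification of pooled
amplicon reads works by best-hit comparison against the amplicon-sized
sub-regions of these references, so this module also locates the template
primer binding sites and cuts out the inter-primer region.

FASTA header dialect: ``>specimen_id|species name|gene`` — pipe-separated
because binomials and morphospecies labels ("Genus sp.X") contain spaces.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequtil import PrimerMatch, find_primer, iupac_match, revcomp  # noqa: F401  (re-exported)

GENES = ("COI", "CytB")

# Universal GC-rich tails joining the template primer to the MID-bearing
# fusion primer in the two-step PCR design.
TAIL1 = "CAGGACCAGGGTACGGTG"
TAIL2 = "CGCAGAGAGGCTCCGTG"


@dataclass(frozen=True)
class SpeciesRecord:
    """One reference specimen's sequence for one gene."""

    specimen_id: str
    species: str
    gene: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise ValueError(f"unsupported gene {self.gene!r}; expected one of {GENES}")
        if not self.species:
            raise ValueError("species label must be non-empty")
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"empty sequence for specimen {self.specimen_id!r}")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"non-ACGTN characters in {self.specimen_id!r}: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class PrimerSet:
    """A template-specific primer pair and the amplicon it defines.

    ``fwd`` and ``rev`` are 5'→3' on opposite strands (standard PCR
    convention); ``expected_amplicon_length`` is the inter-primer insert
    length with primers trimmed off.
    """

    name: str
    fwd: str
    rev: str
    gene: str
    expected_amplicon_length: int

    def __post_init__(self) -> None:
        for p in (self.fwd, self.rev):
            for c in p:
                if c not in "ACGTRYSWKMBDHVN":
                    raise ValueError(f"invalid IUPAC code {c!r} in primer {self.name}")
        if self.expected_amplicon_length <= 0:
            raise ValueError("expected_amplicon_length must be > 0")


#: Template-specific primer pairs used for the pooled amplicon runs:
#: COIAfor/LCO1490 yield a 395 bp COI insert, CB1/CB322R a 343 bp CytB insert.
COI_PRIMERS = PrimerSet(
    name="COIAfor/LCO1490",
    fwd="CCHCGAATAAATAATATAAGWTTYTG",
    rev="GGTCAACAAATCATAAAGATATTGG",
    gene="COI",
    expected_amplicon_length=395,
)
CYTB_PRIMERS = PrimerSet(
    name="CB1/CB322R",
    fwd="TATGTTTTACCATGAGGACAAATATC",
    rev="GGRTTDGCDGGRATRAARTTATC",
    gene="CytB",
    expected_amplicon_length=343,
)
DEFAULT_PRIMER_SETS = (COI_PRIMERS, CYTB_PRIMERS)


class ReferenceDB:
    """An indexed collection of :class:`SpeciesRecord`.

    Specimen ids are unique per gene; a species may have any number of
    records per gene (intraspecific haplotype variation).
    """

    def __init__(self, records: Iterable[SpeciesRecord] = ()) -> None:
        self.records: list[SpeciesRecord] = []
        self._by_gene_id: dict[tuple[str, str], SpeciesRecord] = {}
        self.species_index: dict[str, dict[str, list[SpeciesRecord]]] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SpeciesRecord) -> None:
        key = (rec.gene, rec.specimen_id)
        if key in self._by_gene_id:
            raise ValueError(
                f"duplicate specimen_id {rec.specimen_id!r} for gene {rec.gene}"
            )
        self._by_gene_id[key] = rec
        self.records.append(rec)
        self.species_index.setdefault(rec.species, {}).setdefault(rec.gene, []).append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpeciesRecord]:
        return iter(self.records)

    def by_gene(self, gene: str) -> list[SpeciesRecord]:
        return [r for r in self.records if r.gene == gene]

    def species(self, gene: str | None = None) -> list[str]:
        if gene is None:
            return sorted(self.species_index)
        return sorted(s for s, g in self.species_index.items() if gene in g)

    def records_for(self, species: str, gene: str) -> list[SpeciesRecord]:
        return self.species_index.get(species, {}).get(gene, [])

    # ---- persistence -----------------------------------------------------
    def write_fasta(self, path: str | Path) -> None:
        recs = [
            SeqRecord(Seq(r.sequence), id=f"{r.specimen_id}|{r.species}|{r.gene}", description="")
            for r in self.records
        ]
        SeqIO.write(recs, str(path), "fasta")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "bulkbarcode-refdb",
            "version": 1,
            "records": [
                {
                    "specimen_id": r.specimen_id,
                    "species": r.species,
                    "gene": r.gene,
                    "sequence": r.sequence,
                    "source": r.source,
                }
                for r in self.records
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceDB":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "bulkbarcode-refdb":
            raise ValueError(f"{path}: not a bulkbarcode reference DB")
        return cls(SpeciesRecord(**r) for r in payload["records"])


def _parse_header(header: str, default_gene: str | None) -> tuple[str, str, str]:
    parts = header.split("|")
    if len(parts) == 3:
        sid, species, gene = (p.strip() for p in parts)
    elif len(parts) == 2 and default_gene is not None:
        sid, species = (p.strip() for p in parts)
        gene = default_gene
    else:
        raise ValueError(
            f"malformed FASTA header {header!r}: expected 'specimen_id|species|gene'"
            + ("" if default_gene else " (or 'specimen_id|species' with an explicit gene argument)")
        )
    if not sid or not species:
        raise ValueError(f"malformed FASTA header {header!r}: empty specimen_id or species")
    return sid, species, gene


def load_reference_fasta(path: str | Path, gene: str | None = None) -> ReferenceDB:
    """Load a reference library from FASTA.

    Headers follow ``specimen_id|species|gene``; two-field headers are
    accepted when ``gene`` is given. Sequences are uppercased. Malformed
    headers and duplicate specimen ids raise with the offending header/id.
    """
    db = ReferenceDB()
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        header = rec.description or rec.id
        sid, species, g = _parse_header(header, gene)
        db.add(SpeciesRecord(specimen_id=sid, species=species, gene=g, sequence=str(rec.seq)))
    if n == 0:
        raise ValueError(f"{path}: empty or unparseable FASTA")
    return db


@dataclass
class ExtractionReport:
    """Records skipped during amplicon extraction, with the reason."""

    skipped: list[tuple[str, str]] = field(default_factory=list)  # (specimen_id, reason)


def extract_amplicon(
    record: SpeciesRecord,
    primers: PrimerSet,
    max_mismatches: int = 2,
    length_tolerance: int = 12,
) -> str:
    """Cut the inter-primer region out of a full-length reference sequence.

    The forward primer is searched on the given strand and the reverse
    primer as its reverse complement downstream; both are trimmed off. The
    insert length must fall within ``length_tolerance`` of the primer set's
    expected amplicon length (mitochondrial inserts vary a little in
    length, CytB in particular).
    """
    seq = record.sequence
    fwd = find_primer(seq, primers.fwd, max_mismatches)
    if fwd is None:
        raise ValueError(f"{record.specimen_id}: forward primer {primers.name} not found")
    start = fwd.position + len(primers.fwd)
    rev = find_primer(seq[start:], revcomp(primers.rev), max_mismatches)
    if rev is None:
        raise ValueError(f"{record.specimen_id}: reverse primer {primers.name} not found")
    insert = seq[start : start + rev.position]
    if abs(len(insert) - primers.expected_amplicon_length) > length_tolerance:
        raise ValueError(
            f"{record.specimen_id}: insert length {len(insert)} outside "
            f"{primers.expected_amplicon_length}±{length_tolerance}"
        )
    return insert


def extract_db_amplicons(
    db: ReferenceDB,
    primer_sets: Iterable[PrimerSet] = DEFAULT_PRIMER_SETS,
    max_mismatches: int = 2,
    length_tolerance: int = 12,
) -> tuple[ReferenceDB, ExtractionReport]:
    """Build the amplicon-region sub-database used for read identification.

    References where a primer site cannot be located (or the insert length
    is implausible) are excluded and listed in the report rather than
    silently dropped.
    """
    by_gene = {p.gene: p for p in primer_sets}
    out = ReferenceDB()
    report = ExtractionReport()
    for rec in db:
        primers = by_gene.get(rec.gene)
        if primers is None:
            report.skipped.append((rec.specimen_id, f"no primer set for gene {rec.gene}"))
            continue
        try:
            insert = extract_amplicon(rec, primers, max_mismatches, length_tolerance)
        except ValueError as exc:
            report.skipped.append((rec.specimen_id, str(exc)))
            continue
        out.add(SpeciesRecord(rec.specimen_id, rec.species, rec.gene, insert, rec.source))
    return out, report
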