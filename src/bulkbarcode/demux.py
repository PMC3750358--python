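"""Sort multiplexed reads into samples by dual MID tags; trim and orient.

A read is binned to a sample only when *both* its forward and reverse MID
match that sample's pair — reads whose two tags belong to different
samples are the signature of mis-tagging (tag jumping) and are rejected
and tallied, since keeping them would plant species into the wrong
sample. MID matching is exact: tags are short and designed with mutual
Hamming distance ≥3, and exactness maximises mis-tag detection.

After binning, the universal tails and template primers are trimmed off
(IUPAC-aware, up to 2 mismatches), reverse-direction reads are
reverse-complemented into reference orientation, and each insert is
assigned a gene by length (COI ≈ 395 bp vs CytB ≈ 343 bp).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .refdb import DEFAULT_PRIMER_SETS, PrimerSet
from .sequtil import find_primer, revcomp
from .sim454 import MidScheme

STATUS_ASSIGNED = "assigned"
STATUS_REJECTED_MID = "rejected_mid"
STATUS_REJECTED_STRUCTURE = "rejected_structure"


@dataclass
class TaggedRead:
    read_id: str
    raw: str
    fwd_mid: str = "unknown"
    rev_mid: str = "unknown"
    orientation: str = "as-is"  # as-is | revcomp
    direction: str = ""  # forward | reverse (which fusion primer began the read)
    insert: str = ""
    gene: str = ""  # COI | CytB | ambiguous
    status: str = ""
    sample: str = ""
    reject_reason: str = ""


@dataclass
class DemuxResult:
    bins: dict[str, list[TaggedRead]] = field(default_factory=dict)
    rejects: list[TaggedRead] = field(default_factory=list)
    mistag_count: int = 0
    unknown_mid_count: int = 0

    @property
    def n_binned(self) -> int:
        return sum(len(v) for v in self.bins.values())

    @property
    def n_total(self) -> int:
        return self.n_binned + len(self.rejects)

    def report(self) -> pd.DataFrame:
        """Per-sample per-gene per-direction counts plus reject tallies."""
        rows = []
        for sample in sorted(self.bins):
            tally: dict[tuple[str, str], int] = {}
            for r in self.bins[sample]:
                tally[(r.gene, r.direction)] = tally.get((r.gene, r.direction), 0) + 1
            for (gene, direction), n in sorted(tally.items()):
                rows.append(
                    {"sample": sample, "gene": gene, "direction": direction, "reads": n}
                )
        reasons: dict[str, int] = {}
        for r in self.rejects:
            reasons[r.reject_reason] = reasons.get(r.reject_reason, 0) + 1
        for reason, n in sorted(reasons.items()):
            rows.append({"sample": "(rejected)", "gene": reason, "direction": "", "reads": n})
        return pd.DataFrame(rows, columns=["sample", "gene", "direction", "reads"])


def assign_gene(
    insert: str,
    primer_sets: Sequence[PrimerSet] = DEFAULT_PRIMER_SETS,
    window: int = 15,
) -> str:
    """Classify an insert as COI/CytB by length, 'ambiguous' if neither or both.

    The default ±15 bp window separates the 343 bp and 395 bp amplicons
    with margin for homopolymer indels.
    """
    if not insert:
        raise ValueError("empty insert")
    hits = [p.gene for p in primer_sets if abs(len(insert) - p.expected_amplicon_length) <= window]
    return hits[0] if len(hits) == 1 else "ambiguous"


def trim_and_orient(
    read: TaggedRead,
    mids: MidScheme,
    primer_sets: Sequence[PrimerSet] = DEFAULT_PRIMER_SETS,
    primer_mismatches: int = 2,
) -> TaggedRead:
    """Strip MIDs, tails and template primers; record direction.

    Assumes orientation and MIDs were already detected (``read.orientation``
    set); works on the reference-oriented sequence. The forward template
    primer is searched just after the 5' MID+tail, the reverse primer (as
    reverse complement) near the 3' end. Failure to locate a primer on
    either end → ``rejected_structure``.
    """
    seq = read.raw if read.orientation == "as-is" else revcomp(read.raw)
    L = mids.mid_length
    inner = seq[L:-L] if len(seq) > 2 * L else ""
    # leading universal tail (tolerate a couple of mismatches, small offset)
    head = None
    for primers in primer_sets:
        t = find_primer(inner[: len(mids.tail1) + 4], mids.tail1, primer_mismatches)
        if t is None:
            continue
        after_tail = t.position + len(mids.tail1)
        p = find_primer(
            inner[after_tail : after_tail + len(primers.fwd) + 4],
            primers.fwd,
            primer_mismatches,
        )
        if p is None:
            continue
        start = after_tail + p.position + len(primers.fwd)
        # 3' end: reverse primer then tail2, both reverse-complemented
        tail_rc = revcomp(mids.tail2)
        prim_rc = revcomp(primers.rev)
        tail_zone = inner[-(len(tail_rc) + 4) :]
        t2 = find_primer(tail_zone, tail_rc, primer_mismatches)
        if t2 is None:
            continue
        end_tail = len(inner) - len(tail_zone) + t2.position
        prim_zone = inner[max(start, end_tail - len(prim_rc) - 4) : end_tail]
        p2 = find_primer(prim_zone, prim_rc, primer_mismatches)
        if p2 is None:
            continue
        end = max(start, end_tail - len(prim_rc) - 4) + p2.position
        head = (start, end)
        break
    if head is None or head[1] <= head[0]:
        read.status = STATUS_REJECTED_STRUCTURE
        read.reject_reason = "primer_not_found"
        return read
    read.insert = inner[head[0] : head[1]]
    read.direction = "forward" if read.orientation == "as-is" else "reverse"
    return read


def _detect_mids(seq: str, mids: MidScheme) -> tuple[str, str, str]:
    """Try both orientations; return (orientation, fwd_mid, rev_mid).

    A tag is reported as found only on exact membership in the scheme's
    tag pools; unknown tags come back as 'unknown'.
    """
    L = mids.mid_length
    fwd_set, rev_set = mids.forward_mids, mids.reverse_mids
    best = ("as-is", "unknown", "unknown", -1)
    for orientation in ("as-is", "revcomp"):
        s = seq if orientation == "as-is" else revcomp(seq)
        if len(s) < 2 * L:
            continue
        f, r = s[:L], revcomp(s[-L:])
        fm = f if f in fwd_set else "unknown"
        rm = r if r in rev_set else "unknown"
        score = (fm != "unknown") + (rm != "unknown")
        if score > best[3]:
            best = (orientation, fm, rm, score)
    return best[0], best[1], best[2]


def demultiplex(
    reads: Iterable[tuple[str, str]],
    mids: MidScheme,
    primer_sets: Sequence[PrimerSet] = DEFAULT_PRIMER_SETS,
    primer_mismatches: int = 2,
    gene_window: int = 15,
) -> DemuxResult:
    """Bin reads by MID pair, trim, orient, and assign genes.

    Every input read ends up in exactly one sample bin or the reject
    pile. Rejects are classified: ``mistag`` (both tags known but not a
    sample's pair — the tag-jump signature), ``unknown_mid`` (a tag not in
    the scheme), or structural (primers/tails unlocatable).
    """
    if not mids.samples:
        raise ValueError("empty MID scheme")
    result = DemuxResult()
    result.bins = {s: [] for s in mids.samples}
    for read_id, seq in reads:
        tr = TaggedRead(read_id=read_id, raw=seq)
        tr.orientation, tr.fwd_mid, tr.rev_mid = _detect_mids(seq, mids)
        sample = (
            mids.sample_of(tr.fwd_mid, tr.rev_mid)
            if "unknown" not in (tr.fwd_mid, tr.rev_mid)
            else None
        )
        if sample is None:
            tr.status = STATUS_REJECTED_MID
            if "unknown" in (tr.fwd_mid, tr.rev_mid):
                tr.reject_reason = "unknown_mid"
                result.unknown_mid_count += 1
            else:
                tr.reject_reason = "mistag"
                result.mistag_count += 1
            result.rejects.append(tr)
            continue
        tr = trim_and_orient(tr, mids, primer_sets, primer_mismatches)
        if tr.status == STATUS_REJECTED_STRUCTURE:
            result.rejects.append(tr)
            continue
        tr.sample = sample
        tr.status = STATUS_ASSIGNED
        tr.gene = assign_gene(tr.insert, primer_sets, gene_window)
        result.bins[sample].append(tr)
    return result
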