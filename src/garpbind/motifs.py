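"""CRM/ECRM motif scanning and the CRM-inactivating mutation rule.

B-type ARR transcription factors recognize the cytokinin response motif
(CRM) 5'-(A/G)GAT(T/C)-3' (IUPAC RGATY); some require the extended motif
(ECRM) AAGAT(T/C)TT for full activation.  Both strands of an input sequence
are scanned and hits are reported in sense-strand, 0-based, half-open
coordinates (BED-compatible).  The mutation rule inactivates every CRM by
replacing the invariant GA dinucleotide (positions 2-3 of the motif in its
own orientation) with CT -- equivalently, TC -> AG on the ATC-bearing
complementary strand -- which turns the wild-type ARR5-promoter oligo into
its binding-dead mutant.

Ambiguity codes other than A/C/G/T never match (conservative calling).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: 45-nt ARR5-promoter fragment used for the binding assays (wild type):
#: four core CRM sites over both strands, one of them inside the single ECRM.
ARR5_WT_OLIGO = "ttaacAATCTcaaAGATTttgtAGATTgaaatacaAATCTtctct"

#: The CRM-inactivated mutant of :data:`ARR5_WT_OLIGO` (TC -> AG rule).
ARR5_MUT_OLIGO = "ttaacAAagTcaaActTTttgtActTTgaaatacaAAagTtctct"

CRM_PATTERN = re.compile(r"(?=([AG]GAT[TC]))")
ECRM_PATTERN = re.compile(r"(?=(AAGAT[TC]TT))")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

MOTIF_WIDTH = {"CRM": 5, "ECRM": 8}


def revcomp(seq: str) -> str:
    """Reverse complement (uppercase A/C/G/T only; others pass through)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence in sense-strand 0-based half-open coordinates."""

    start: int
    end: int
    strand: str       # '+' or '-'
    kind: str         # 'CRM' or 'ECRM'
    matched_seq: str  # sense-strand slice, uppercase

    def __post_init__(self):
        if self.end - self.start != MOTIF_WIDTH[self.kind]:
            raise ValueError(f"{self.kind} hit must span {MOTIF_WIDTH[self.kind]} nt")


def _scan(seq: str, pattern: re.Pattern, kind: str) -> list[MotifHit]:
    s = seq.upper()
    width = MOTIF_WIDTH[kind]
    hits = []
    for m in pattern.finditer(s):
        hits.append(MotifHit(m.start(), m.start() + width, "+", kind, m.group(1)))
    rc = revcomp(s)
    n = len(s)
    for m in pattern.finditer(rc):
        start = n - (m.start() + width)
        hits.append(MotifHit(start, start + width, "-", kind, s[start:start + width]))
    # a palindromic occurrence would be reported once per strand; the motifs
    # here are non-palindromic so +/- hits never coincide
    return sorted(hits, key=lambda h: (h.start, h.strand))


def scan_crm(seq: str) -> list[MotifHit]:
    """All CRM (RGATY) occurrences on both strands, ascending by start."""
    return _scan(seq, CRM_PATTERN, "CRM")


def scan_ecrm(seq: str) -> list[MotifHit]:
    """All ECRM (AAGAT(T/C)TT) occurrences on both strands."""
    return _scan(seq, ECRM_PATTERN, "ECRM")


def count_motifs(seq: str) -> tuple[int, int]:
    """(standalone CRM count, ECRM count) over both strands.

    A CRM lying entirely inside an ECRM hit is not counted separately --
    the counting convention under which the wild-type oligo's four core
    sites read as "three CRMs and one ECRM".
    """
    crms = scan_crm(seq)
    ecrms = scan_ecrm(seq)
    standalone = [
        h for h in crms
        if not any(e.start <= h.start and h.end <= e.end for e in ecrms)
    ]
    return len(standalone), len(ecrms)


def mutate_crm_sites(seq: str) -> str:
    """Inactivate every CRM by the GA -> CT (i.e. TC -> AG) replacement.

    For each CRM hit the edit is applied in the hit's own orientation at
    motif positions 2-3 and reflected back to the sense strand for minus
    hits; the output is uppercase and idempotent (it scans to zero CRMs).
    Overlapping CRM hits whose edits would conflict raise a ValueError
    listing the positions.
    """
    out = seq.upper()
    # a single pass clears every pre-existing CRM; in rare layouts an edit
    # can juxtapose bases into a fresh match, so iterate to closure
    for _ in range(8):
        if not scan_crm(out):
            return out
        out = _mutate_once(out)
    if scan_crm(out):
        raise ValueError("CRM mutation did not reach closure")
    return out


def _mutate_once(seq: str) -> str:
    s = list(seq.upper())
    edits: dict[int, str] = {}

    def put(pos: int, base: str, hit: MotifHit):
        if pos in edits and edits[pos] != base:
            raise ValueError(
                f"conflicting CRM edits at sense position {pos} "
                f"(hit {hit.start}-{hit.end}{hit.strand})"
            )
        edits[pos] = base

    for hit in scan_crm(seq):
        if hit.strand == "+":
            # motif RGATY: replace G(1)A(2) with C T
            put(hit.start + 1, "C", hit)
            put(hit.start + 2, "T", hit)
        else:
            # same replacement in the minus-strand motif frame; on the
            # sense strand the complementary T C (motif pos 2-3 from the
            # right) become A G
            put(hit.end - 2, "G", hit)
            put(hit.end - 3, "A", hit)
    for pos, base in edits.items():
        s[pos] = base
    return "".join(s)


# ---------------------------------------------------------------------------
# File interchange


def scan_fasta(path) -> "pandas.DataFrame":  # noqa: F821
    """Scan every record of a FASTA file; TSV-ready hit table."""
    import pandas as pd
    from Bio import SeqIO

    rec = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq)
        for hit in scan_crm(seq) + scan_ecrm(seq):
            rec.append(
                {
                    "seq_id": entry.id,
                    "start": hit.start,
                    "end": hit.end,
                    "strand": hit.strand,
                    "kind": hit.kind,
                    "matched_seq": hit.matched_seq,
                }
            )
    return pd.DataFrame.from_records(
        rec, columns=["seq_id", "start", "end", "strand", "kind", "matched_seq"]
    )


def hits_to_bed(df) -> str:
    """BED6 text for a hit table from :func:`scan_fasta`."""
    lines = []
    for row in df.itertuples(index=False):
        lines.append(
            f"{row.seq_id}\t{row.start}\t{row.end}\t{row.kind}\t0\t{row.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
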