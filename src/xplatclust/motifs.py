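"""IUPAC promoter motif scanning (the CCRE search).

Promoter regions arrive as fixed-length FASTA written 5'->3' and ending at
the base immediately adjacent to the ORF start.  Motifs are IUPAC nucleotide
strings (R = A/G, Y = C/T, ... N = any).  An ``N`` in a *sequence* is an
unknown base and matches only a pattern ``N``; a pattern ``N`` matches any
sequence character.

Hit positions are reported as nt upstream of the ORF start, measured from
the base immediately 5' of the start codon (offset 1) to the motif's
3'-most base — on the + strand that is the rightmost base of the match, on
the - strand the leftmost (the - strand motif reads right-to-left).  The
anchor base is a declared convention of this package; an "offset 248" hit
in an 800-nt region therefore ends at region position 553.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

__all__ = ["MotifDefinition", "MotifHit", "scan_promoters", "presence_table",
           "read_motifs_tsv", "reverse_complement_pattern"]

# what each IUPAC pattern character accepts in a sequence (sequence N only
# matched by pattern N)
IUPAC_MATCHES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement_pattern(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (R<->Y, K<->M, B<->V, D<->H)."""
    return pattern.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifDefinition:
    """A named IUPAC motif."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"motif {self.name!r}: empty pattern")
        bad = set(self.pattern.upper()) - set(IUPAC_MATCHES)
        if bad:
            raise ValueError(
                f"motif {self.name!r}: illegal IUPAC character(s) {sorted(bad)}"
            )
        object.__setattr__(self, "pattern", self.pattern.upper())

    def regex(self) -> re.Pattern:
        # lookahead so overlapping occurrences are all reported
        body = "".join(f"[{IUPAC_MATCHES[ch]}]" for ch in self.pattern)
        return re.compile(f"(?=({body}))")


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence.

    ``upstream_offset`` is 1-based distance of the motif's 3'-most base from
    the ORF start (adjacent base = 1); ``matched`` is the region subsequence
    covered by the hit (display orientation).
    """

    sequence_id: str
    motif: str
    upstream_offset: int
    strand: str
    matched: str


def scan_promoters(
    regions: list[tuple[str, str]],
    motifs: list[MotifDefinition],
    both_strands: bool = False,
) -> list[MotifHit]:
    """Report every (overlapping) IUPAC match in every region.

    With ``both_strands`` the reverse complement of each pattern is also
    scanned against the displayed sequence and reported on strand '-'.
    Results are sorted by (sequence order, motif order, offset).  Regions
    shorter than every pattern simply yield no hits.
    """
    hits: list[MotifHit] = []
    for rid, seq in regions:
        seq = seq.upper()
        L = len(seq)
        for motif in motifs:
            m = len(motif.pattern)
            for match in motif.regex().finditer(seq):
                start = match.start() + 1  # 1-based leftmost
                end = start + m - 1
                hits.append(
                    MotifHit(rid, motif.name, L - end + 1, "+", seq[start - 1 : end])
                )
            if both_strands:
                rc = MotifDefinition(motif.name, reverse_complement_pattern(motif.pattern))
                for match in rc.regex().finditer(seq):
                    start = match.start() + 1
                    # 3'-most base of the - strand motif = leftmost display base
                    hits.append(
                        MotifHit(
                            rid, motif.name, L - start + 1, "-",
                            seq[start - 1 : start + m - 1],
                        )
                    )
    seq_order = {rid: i for i, (rid, _) in enumerate(regions)}
    motif_order = {mo.name: i for i, mo in enumerate(motifs)}
    hits.sort(key=lambda h: (seq_order[h.sequence_id], motif_order[h.motif], h.upstream_offset))
    return hits


def presence_table(
    hits: list[MotifHit],
    regions: list[tuple[str, str]],
    motifs: list[MotifDefinition],
) -> pd.DataFrame:
    """Per (sequence, motif) hit count and minimum upstream offset.

    Sequences with zero hits appear with count 0 (offset left missing).
    Columns are ``{motif}_count`` and ``{motif}_min_offset``.
    """
    index = pd.Index([rid for rid, _ in regions], name="sequence_id")
    data: dict[str, pd.Series] = {}
    for motif in motifs:
        counts = pd.Series(0, index=index, dtype=int)
        min_off = pd.Series(float("nan"), index=index, dtype=float)
        for h in hits:
            if h.motif != motif.name:
                continue
            counts[h.sequence_id] += 1
            cur = min_off[h.sequence_id]
            if pd.isna(cur) or h.upstream_offset < cur:
                min_off[h.sequence_id] = h.upstream_offset
        data[f"{motif.name}_count"] = counts
        data[f"{motif.name}_min_offset"] = min_off
    return pd.DataFrame(data, index=index)


def read_motifs_tsv(path) -> list[MotifDefinition]:
    """Read a ``name<TAB>iupac_pattern`` TSV (optional header)."""
    motifs: list[MotifDefinition] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] in ("name", "motif"):
                continue
            if len(parts) != 2:
                raise ValueError(f"{path}: malformed motif row at line {lineno}")
            motifs.append(MotifDefinition(name=parts[0], pattern=parts[1]))
    if not motifs:
        raise ValueError(f"{path}: no motifs")
    return motifs
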