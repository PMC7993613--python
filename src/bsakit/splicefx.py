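"""Transcript consequences of a splice-donor mutation.

Given a gene model (exon coordinates over a genomic sequence, 1-based
inclusive, GFF convention), this module checks whether a variant disrupts a
canonical GT donor, scans the intron for cryptic GT donors, builds
intron-retention isoforms (the retained length for a cryptic donor at
0-based intron offset k is exactly k), annotates frame and premature-stop
status by translation, and reports the peptide-level consequence.

Minus-strand genes are reverse-complemented to transcript orientation before
any scanning, so intron offsets are always 5'->3' of the transcript.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "IsoformModel",
    "ConsequenceRecord",
    "check_donor",
    "scan_cryptic_donors",
    "build_isoforms",
    "junction_signature",
    "peptide_consequence",
    "example_gene",
    "apply_donor_mutation",
]

SIGNATURE_FLANK = 15
SIGNATURE_MAX_LEN = 60


@dataclass(frozen=True)
class GeneModel:
    """A gene over an explicit genomic sequence.

    ``sequence`` covers [region_start, region_start + len - 1] on the given
    chromosome; ``exons`` are 1-based inclusive genomic coordinate pairs,
    non-overlapping and ordered by position. ``cds_start`` is the 0-based
    offset of the first coding base within the spliced transcript (after
    orientation). Introns whose oriented sequence does not start GT / end AG
    are flagged in ``noncanonical_introns`` rather than rejected.
    """

    gene_id: str
    chrom: str
    region_start: int  # 1-based genomic coordinate of sequence[0]
    sequence: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"
    cds_start: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon ({s}, {e}) has start > end")
            if prev_end is not None and s <= prev_end:
                raise ValueError("exons must be ordered and non-overlapping")
            prev_end = e
        lo = self.exons[0][0]
        hi = self.exons[-1][1]
        if lo < self.region_start or hi > self.region_start + len(self.sequence) - 1:
            raise ValueError("exons fall outside the provided sequence")

    # -- oriented (transcript 5'->3') views ---------------------------------

    def _oriented_seq(self) -> str:
        if self.strand == "+":
            return self.sequence
        return str(Seq(self.sequence).reverse_complement())

    def _oriented_exons(self) -> list[tuple[int, int]]:
        """Exons as 0-based half-open offsets into the oriented sequence."""
        n = len(self.sequence)
        out = []
        for s, e in self.exons:
            a, b = s - self.region_start, e - self.region_start + 1
            if self.strand == "-":
                a, b = n - b, n - a
            out.append((a, b))
        if self.strand == "-":
            out.reverse()
        return out

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def exon_seqs(self) -> list[str]:
        seq = self._oriented_seq()
        return [seq[a:b] for a, b in self._oriented_exons()]

    def intron_seqs(self) -> list[str]:
        seq = self._oriented_seq()
        ex = self._oriented_exons()
        return [seq[ex[i][1] : ex[i + 1][0]] for i in range(len(ex) - 1)]

    def noncanonical_introns(self) -> list[int]:
        """Indices of introns violating the GT...AG rule (flag, not fatal)."""
        bad = []
        for i, intron in enumerate(self.intron_seqs()):
            if not (intron.startswith("GT") and intron.endswith("AG")):
                bad.append(i)
        return bad

    def mrna(self) -> str:
        return "".join(self.exon_seqs())

    def cds(self) -> str:
        return self.mrna()[self.cds_start :]

    def to_transcript_offset(self, pos: int) -> int:
        """Map a 1-based genomic position to a 0-based oriented-sequence offset."""
        off = pos - self.region_start
        if not 0 <= off < len(self.sequence):
            raise ValueError(f"position {pos} outside the gene sequence")
        if self.strand == "-":
            off = len(self.sequence) - off - 1
        return off

    # -- serialisation -------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "gene_id": self.gene_id,
                "chrom": self.chrom,
                "region_start": self.region_start,
                "sequence": self.sequence,
                "exons": [list(e) for e in self.exons],
                "strand": self.strand,
                "cds_start": self.cds_start,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GeneModel":
        d = json.loads(text)
        return cls(
            gene_id=d["gene_id"],
            chrom=d["chrom"],
            region_start=int(d["region_start"]),
            sequence=d["sequence"].upper(),
            exons=tuple(tuple(e) for e in d["exons"]),
            strand=d.get("strand", "+"),
            cds_start=int(d.get("cds_start", 0)),
        )


@dataclass(frozen=True)
class IsoformModel:
    """A transcript variant retaining ``retained_len`` intronic nucleotides.

    ``junction_signature`` is the sequence window spanning the novel (or
    canonical) junction; ``sequence`` is the full spliced mRNA.
    """

    isoform_id: str
    retained_len: int
    junction_signature: str
    in_frame: bool
    premature_stop: bool
    sequence: str
    cds_start: int = 0

    def __post_init__(self) -> None:
        if self.retained_len < 0:
            raise ValueError("retained_len must be >= 0")
        if not self.junction_signature:
            raise ValueError("junction_signature must be nonempty")
        if self.in_frame != (self.retained_len % 3 == 0):
            raise ValueError("in_frame inconsistent with retained_len")

    def translation(self) -> str:
        cds = self.sequence[self.cds_start :]
        cds = cds[: len(cds) - len(cds) % 3]
        return str(Seq(cds).translate())


def _intron_or_raise(gene: GeneModel, intron_index: int) -> str:
    if not 0 <= intron_index < gene.n_introns:
        raise IndexError(f"intron index {intron_index} out of range")
    return gene.intron_seqs()[intron_index]


def check_donor(gene: GeneModel, intron_index: int, pos: int, ref: str, alt: str) -> str:
    """Status of a splice donor given a variant: intact, disrupted, non_canonical.

    The donor is the first two intronic bases (transcript orientation). A
    variant disrupts it iff it changes position +1 away from G or +2 away
    from T. A reference donor that is not GT is reported non_canonical.
    """
    intron = _intron_or_raise(gene, intron_index)
    donor = intron[:2]
    if donor != "GT":
        return "non_canonical"
    ex = gene._oriented_exons()
    intron_start = ex[intron_index][1]
    off = gene.to_transcript_offset(pos) - intron_start
    if gene.strand == "-":
        ref = str(Seq(ref).reverse_complement())
        alt = str(Seq(alt).reverse_complement())
    if off in (0, 1):
        if intron[off] != ref:
            raise ValueError(
                f"variant ref {ref!r} does not match intron base {intron[off]!r} at +{off + 1}"
            )
        mutated = (alt + intron[1]) if off == 0 else (intron[0] + alt)
        return "intact" if mutated == "GT" else "disrupted"
    return "intact"


def scan_cryptic_donors(intron_seq: str) -> list[int]:
    """Ascending 0-based offsets of every GT dinucleotide in the intron.

    Overlapping occurrences all count; a cryptic donor at offset k retains
    the first k intronic nucleotides in the transcript.
    """
    if not intron_seq:
        raise ValueError("intron sequence must be nonempty")
    return [i for i in range(len(intron_seq) - 1) if intron_seq[i : i + 2] == "GT"]


def junction_signature(
    gene: GeneModel,
    intron_index: int,
    retained_len: int,
    flank: int = SIGNATURE_FLANK,
    max_len: int = SIGNATURE_MAX_LEN,
) -> str:
    """Sequence window spanning the (possibly novel) exon junction.

    ``flank`` bases of the upstream exon, the retained intronic prefix, then
    ``flank`` bases of the downstream exon; truncated to ``max_len`` from the
    left so the signature stays contiguous within the transcript.
    """
    exons = gene.exon_seqs()
    intron = _intron_or_raise(gene, intron_index)
    sig = exons[intron_index][-flank:] + intron[:retained_len] + exons[intron_index + 1][:flank]
    return sig[:max_len]


def _splice(gene: GeneModel, intron_index: int, retained_len: int) -> str:
    exons = gene.exon_seqs()
    intron = _intron_or_raise(gene, intron_index)
    if retained_len > len(intron):
        raise ValueError("retained length exceeds intron length")
    parts = exons[: intron_index + 1] + [intron[:retained_len]] + exons[intron_index + 1 :]
    return "".join(parts)


def _has_premature_stop(cds: str) -> bool:
    """True iff an in-frame stop codon occurs before the final complete codon."""
    usable = len(cds) - len(cds) % 3
    aa = str(Seq(cds[:usable]).translate())
    first = aa.find("*")
    return first != -1 and first < len(aa) - 1


def build_isoforms(
    gene: GeneModel,
    intron_index: int,
    offsets,
    include_canonical: bool = True,
    flank: int = SIGNATURE_FLANK,
    max_sig_len: int = SIGNATURE_MAX_LEN,
) -> list[IsoformModel]:
    """One canonical isoform plus one intron-retention isoform per offset.

    Offsets come from scan_cryptic_donors (or the caller); frame and
    premature-stop status are derived by translating each spliced coding
    sequence from the annotated start.
    """
    intron = _intron_or_raise(gene, intron_index)
    retained = ([0] if include_canonical else []) + list(offsets)
    out = []
    for j, k in enumerate(retained):
        if k > len(intron):
            raise ValueError(f"offset {k} beyond intron length {len(intron)}")
        mrna = _splice(gene, intron_index, k)
        cds = mrna[gene.cds_start :]
        iso_id = "canonical" if k == 0 else f"retained_{k}"
        out.append(
            IsoformModel(
                isoform_id=iso_id,
                retained_len=k,
                junction_signature=junction_signature(gene, intron_index, k, flank, max_sig_len),
                in_frame=(k % 3 == 0),
                premature_stop=_has_premature_stop(cds),
                sequence=mrna,
                cds_start=gene.cds_start,
            )
        )
    return out


@dataclass(frozen=True)
class ConsequenceRecord:
    """Peptide-level consequence of one isoform."""

    kind: str  # identity | insertion | truncation
    inserted_aa: int = 0
    truncation_codon: int | None = None  # 1-based codon of the first stop


def peptide_consequence(isoform: IsoformModel, gene: GeneModel) -> ConsequenceRecord:
    """Classify an isoform's effect on the encoded protein.

    In-frame retention without a premature stop inserts retained_len/3 amino
    acids; a frameshift or premature in-frame stop truncates at the first
    stop codon; zero retention is identity.
    """
    if gene.cds_start >= len(gene.mrna()):
        raise ValueError("gene model lacks a coding start within the transcript")
    if isoform.retained_len == 0:
        return ConsequenceRecord("identity")
    if isoform.in_frame and not isoform.premature_stop:
        return ConsequenceRecord("insertion", inserted_aa=isoform.retained_len // 3)
    aa = isoform.translation()
    first = aa.find("*")
    return ConsequenceRecord("truncation", truncation_codon=None if first == -1 else first + 1)


def apply_donor_mutation(gene: GeneModel, intron_index: int, alt: str = "A") -> GeneModel:
    """Return a copy of the gene with the first donor base of the given
    intron replaced (GT -> alt+T), in transcript orientation."""
    intron = _intron_or_raise(gene, intron_index)
    seq = gene._oriented_seq()
    ex = gene._oriented_exons()
    i = ex[intron_index][1]
    mutated = seq[:i] + alt + seq[i + 1 :]
    if gene.strand == "-":
        mutated = str(Seq(mutated).reverse_complement())
    return GeneModel(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        region_start=gene.region_start,
        sequence=mutated,
        exons=gene.exons,
        strand=gene.strand,
        cds_start=gene.cds_start,
    )


def example_gene(strand: str = "+") -> GeneModel:
    """Deterministic three-exon gene engineered for the retention scenarios.

    The second intron starts GT and carries cryptic GT donors at offsets 8,
    15 and 221: retention of 8 nt shifts frame into an immediate downstream
    stop, retention of 15 nt is in frame with no stop (five inserted amino
    acids), and retention of 221 nt shifts frame and contains an in-frame
    stop within the retained segment.
    """
    e1 = "ATG" + "GCA" * 19  # 60 nt, Met + poly-Ala
    i0 = "GT" + "A" * 26 + "AG"  # 30 nt, plain canonical intron
    e2 = "GAC" * 15 + "TGCCGCAAGGAAGCC"  # 60 nt; distinctive 15 nt tail
    head = "GTAAGCAAGTCGCACGT"  # GT donors at offsets 0, 8, 15
    i1 = head + "ACAC" + "TAA" + "CA" * 98 + "C" + "GT" + "AACCCACCCACCCAAAG"
    e3 = "CTAAACGCCGCCAAA" + "GCC" * 15 + "TAA"  # 63 nt; stop at +2 frameshift
    assert len(i1) == 240 and i1[221:223] == "GT" and i1.endswith("AG")
    assert scan_cryptic_donors(i1) == [0, 8, 15, 221]
    seq = e1 + i0 + e2 + i1 + e3
    start = 101
    bounds = []
    off = 0
    for part in (e1, i0, e2, i1, e3):
        bounds.append((off, off + len(part)))
        off += len(part)
    exons = tuple(
        (start + a, start + b - 1) for i, (a, b) in enumerate(bounds) if i % 2 == 0
    )
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
        total = len(seq)
        exons = tuple(
            sorted(
                (start + total - 1 - (e - start), start + total - 1 - (s - start))
                for s, e in exons
            )
        )
    return GeneModel(
        gene_id="demo_gene",
        chrom="chr1",
        region_start=start,
        sequence=seq,
        exons=exons,
        strand=strand,
        cds_start=0,
    )
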