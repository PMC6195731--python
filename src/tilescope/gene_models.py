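"""Gene models, guide enumeration, and guide-to-protein coordinate mapping.

Conventions used throughout the package:

* genomic intervals are 0-based, half-open ``[start, end)``;
* amino-acid and coding-nucleotide positions are 1-based;
* the CDS includes the stop codon, so the protein length is
  ``L = cds_length / 3 - 1``;
* the SpCas9 blunt cut falls 3 bp 5' of the PAM, between protospacer
  positions 17 and 18 (1-based).  A cut coordinate is the 0-based genomic
  position of the base immediately 3' of the break on the + strand.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "Transcript",
    "GeneModel",
    "MrnaFeatures",
    "GuideRecord",
    "cut_site",
    "enumerate_guides",
    "map_cut_to_amino_acids",
    "mrna_features",
    "read_genome",
    "read_gene_models",
    "guides_to_frame",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _iupac_regex(motif: str) -> re.Pattern:
    try:
        pattern = "".join(
            ch if len(IUPAC[ch]) == 1 else "[" + IUPAC[ch] + "]"
            for ch in motif.upper()
        )
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"invalid IUPAC symbol in motif {motif!r}") from exc
    return re.compile(pattern)


@dataclass
class Transcript:
    """One transcript: exon and CDS intervals on the genome.

    ``exons`` and ``cds`` are lists of 0-based half-open ``(start, end)``
    tuples, stored sorted by genomic start regardless of strand.  The CDS
    covers the stop codon; the translated protein length ``L`` excludes it.
    """

    transcript_id: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        self.cds = sorted((int(a), int(b)) for a, b in self.cds)
        for name, ivs in (("exon", self.exons), ("CDS", self.cds)):
            for (a, b) in ivs:
                if a >= b:
                    raise ValueError(f"empty {name} interval ({a}, {b})")
            for (_, b), (a2, _) in zip(ivs, ivs[1:]):
                if a2 < b:
                    raise ValueError(f"overlapping {name} intervals")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"CDS length {self.cds_length} of {self.transcript_id} "
                "is not a multiple of 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds)

    @property
    def protein_length(self) -> int:
        """Number of amino acids, stop codon excluded."""
        return self.cds_length // 3 - 1

    def coding_position(self, genomic: int, strand: str) -> int | None:
        """1-based position of a genomic base within the coding sequence.

        Returns None when the base is not inside the CDS.
        """
        offset = 0
        ivs = self.cds if strand == "+" else self.cds[::-1]
        for a, b in ivs:
            if a <= genomic < b:
                return offset + (genomic - a + 1 if strand == "+" else b - genomic)
            offset += b - a
        return None

    def last_junction_coding_position(self, strand: str) -> int | None:
        """Coding nucleotides 5' of the last junction between coding exons.

        None for transcripts whose CDS lies in a single exon.
        """
        if len(self.cds) < 2:
            return None
        lengths = [b - a for a, b in self.cds]
        if strand == "-":
            lengths = lengths[::-1]
        return sum(lengths[:-1])


@dataclass
class GeneModel:
    """A gene: strand, member transcripts, and the principal isoform."""

    gene_id: str
    contig: str
    strand: str
    transcripts: list[Transcript]
    principal_transcript_id: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        ids = [t.transcript_id for t in self.transcripts]
        if self.principal_transcript_id not in ids:
            raise ValueError(
                f"principal transcript {self.principal_transcript_id!r} "
                f"not among {ids}"
            )

    @property
    def principal(self) -> Transcript:
        for t in self.transcripts:
            if t.transcript_id == self.principal_transcript_id:
                return t
        raise AssertionError("unreachable")


@dataclass
class MrnaFeatures:
    """Transcript-level features of a cut site (principal isoform)."""

    dist_5p_exon_border: int | None = None
    dist_3p_exon_border: int | None = None
    exon_length: int | None = None
    exon_multiple_of_3: bool | None = None
    nmd_escape: bool | None = None
    protein_fraction: float | None = None
    isoform_fraction: float | None = None
    same_strand_as_gene: bool | None = None


@dataclass
class GuideRecord:
    """A single guide: spacer, cut site, and its protein-level mapping."""

    guide_id: str
    spacer: str
    pam: str
    contig: str
    guide_strand: str
    cut_coord: int
    gene_id: str | None = None
    aa1: int | None = None
    aa2: int | None = None
    offtarget_score: float | None = None
    efficiency_score: float | None = None
    mrna: MrnaFeatures = field(default_factory=MrnaFeatures)


def cut_site(protospacer_interval: tuple[int, int], strand: str) -> int:
    """Cut coordinate of a 20-nt protospacer (blunt cut 3 bp 5' of the PAM).

    Returns the 0-based genomic position of the base immediately 3' of the
    break on the + strand.
    """
    start, end = protospacer_interval
    if end - start != 20:
        raise ValueError("protospacer interval must have length 20")
    if strand == "+":
        return start + 17
    if strand == "-":
        return start + 3
    raise ValueError(f"strand must be + or -, got {strand!r}")


def map_cut_to_amino_acids(
    cut_coord: int, transcript: Transcript, gene_strand: str
) -> tuple[int, int] | None:
    """Map a cut to the two amino acids flanking the double-strand break.

    The break lies between genomic positions ``cut_coord - 1`` and
    ``cut_coord``.  Let ``k`` be the 1-based coding position of the base 5'
    of the break on the coding strand; the guide maps to
    ``(ceil(k/3), ceil((k+1)/3))``, collapsing to ``(aa, min(aa+1, L))``
    when both flanking bases share a codon.  Returns None when neither
    flanking base is coding (intron or UTR cut); when only the 3'-flanking
    base is coding, its position is used for ``k``.
    """
    five_prime = cut_coord - 1 if gene_strand == "+" else cut_coord
    three_prime = cut_coord if gene_strand == "+" else cut_coord - 1
    k = transcript.coding_position(five_prime, gene_strand)
    if k is None:
        k = transcript.coding_position(three_prime, gene_strand)
        if k is None:
            return None
    L = transcript.protein_length
    aa1 = -(-k // 3)
    aa2 = -(-(k + 1) // 3)
    if aa1 == aa2:
        aa2 = min(aa1 + 1, L)
    aa1 = min(aa1, L)
    aa2 = min(max(aa2, aa1), L)
    if aa1 < 1:
        return None
    return aa1, aa2


def enumerate_guides(
    genome: Mapping[str, str],
    model: GeneModel,
    pam_motif: str = "NGG",
) -> list[GuideRecord]:
    """Enumerate all guides whose cut site falls in the principal CDS.

    Scans both strands of the gene's contig for 20-nt protospacers followed
    by ``pam_motif``; keeps those that map to amino acids of the principal
    transcript.  Records are deduplicated by
    ``(contig, cut_coord, strand, spacer)``.
    """
    if model.contig not in genome:
        raise KeyError(f"contig {model.contig!r} not in genome")
    seq = str(genome[model.contig]).upper()
    n = len(seq)
    principal = model.principal
    for a, b in principal.cds:
        if a < 0 or b > n:
            raise ValueError(
                f"CDS interval ({a}, {b}) outside contig bounds (0, {n})"
            )
    pam_re = _iupac_regex(pam_motif)
    plen = len(pam_motif)
    records: dict[tuple, GuideRecord] = {}
    counter = 0
    for i in range(n - 20 - plen + 1):
        # + strand: protospacer [i, i+20), PAM [i+20, i+20+plen)
        if pam_re.fullmatch(seq[i + 20 : i + 20 + plen]):
            cc = cut_site((i, i + 20), "+")
            aa = map_cut_to_amino_acids(cc, principal, model.strand)
            if aa is not None:
                key = (model.contig, cc, "+", seq[i : i + 20])
                if key not in records:
                    counter += 1
                    records[key] = GuideRecord(
                        guide_id=f"{model.gene_id}_g{counter}",
                        spacer=seq[i : i + 20],
                        pam=seq[i + 20 : i + 20 + plen],
                        contig=model.contig,
                        guide_strand="+",
                        cut_coord=cc,
                        gene_id=model.gene_id,
                        aa1=aa[0],
                        aa2=aa[1],
                    )
    for i in range(plen, n - 20 + 1):
        # - strand: protospacer [i, i+20) read on -, PAM [i-plen, i)
        if pam_re.fullmatch(reverse_complement(seq[i - plen : i])):
            cc = cut_site((i, i + 20), "-")
            aa = map_cut_to_amino_acids(cc, principal, model.strand)
            if aa is not None:
                key = (model.contig, cc, "-", reverse_complement(seq[i : i + 20]))
                if key not in records:
                    counter += 1
                    records[key] = GuideRecord(
                        guide_id=f"{model.gene_id}_g{counter}",
                        spacer=reverse_complement(seq[i : i + 20]),
                        pam=reverse_complement(seq[i - plen : i]),
                        contig=model.contig,
                        guide_strand="-",
                        cut_coord=cc,
                        gene_id=model.gene_id,
                        aa1=aa[0],
                        aa2=aa[1],
                    )
    return list(records.values())


def mrna_features(guide: GuideRecord, gene: GeneModel) -> MrnaFeatures:
    """Transcript-level features of a guide's cut on the principal isoform.

    ``nmd_escape`` applies the 55-nt rule: a frameshift is predicted to
    escape nonsense-mediated decay unless the cut's coding position lies
    more than 55 nt upstream of the last junction between coding exons
    (single-coding-exon transcripts always escape).  Border distances are
    measured from the coding base 5' of the break to the genomic borders of
    the exon containing it, reported in transcript orientation.
    """
    tx = gene.principal
    strand = gene.strand
    five_prime = guide.cut_coord - 1 if strand == "+" else guide.cut_coord
    anchor = five_prime
    k = tx.coding_position(anchor, strand)
    if k is None:
        anchor = guide.cut_coord if strand == "+" else guide.cut_coord - 1
        k = tx.coding_position(anchor, strand)
    if k is None:
        warnings.warn(
            f"guide {guide.guide_id} does not cut in the CDS of "
            f"{tx.transcript_id}; mRNA features are null",
            stacklevel=2,
        )
        return MrnaFeatures(same_strand_as_gene=guide.guide_strand == strand)

    exon = next((iv for iv in tx.cds if iv[0] <= anchor < iv[1]), None)
    assert exon is not None
    exon_len = exon[1] - exon[0]
    d_left, d_right = anchor - exon[0], exon[1] - 1 - anchor
    d5, d3 = (d_left, d_right) if strand == "+" else (d_right, d_left)

    junction = tx.last_junction_coding_position(strand)
    nmd_escape = junction is None or (junction - k) <= 55

    L = tx.protein_length
    aa1 = guide.aa1 if guide.aa1 is not None else min(-(-k // 3), L)
    n_tx = len(gene.transcripts)
    n_hit = sum(
        1
        for t in gene.transcripts
        if t.coding_position(guide.cut_coord, strand) is not None
        or t.coding_position(guide.cut_coord - 1, strand) is not None
    )
    return MrnaFeatures(
        dist_5p_exon_border=d5,
        dist_3p_exon_border=d3,
        exon_length=exon_len,
        exon_multiple_of_3=exon_len % 3 == 0,
        nmd_escape=nmd_escape,
        protein_fraction=aa1 / L,
        isoform_fraction=n_hit / n_tx,
        same_strand_as_gene=guide.guide_strand == strand,
    )


# ---------------------------------------------------------------------------
# I/O


def read_genome(fasta_path: str) -> dict[str, str]:
    """Load a FASTA file into a contig -> sequence dict."""
    from pyfaidx import Fasta

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fa = Fasta(fasta_path, rebuild=True)
        return {name: str(fa[name][:]) for name in fa.keys()}


def read_gene_models(gff_path: str) -> dict[str, GeneModel]:
    """Parse a GFF3 subset (gene/mRNA/exon/CDS) into GeneModel objects.

    The attribute ``principal=1`` on an mRNA marks the principal isoform;
    absent that, the first mRNA of each gene is principal.
    """
    import gffutils

    db = gffutils.create_db(
        gff_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        transcripts = []
        principal_id = None
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exons = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")]
            cds = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
            transcripts.append(Transcript(mrna.id, exons, cds))
            if mrna.attributes.get("principal", ["0"])[0] == "1":
                principal_id = mrna.id
        if not transcripts:
            continue
        if principal_id is None:
            principal_id = transcripts[0].transcript_id
        genes[gene.id] = GeneModel(
            gene_id=gene.id,
            contig=gene.seqid,
            strand=gene.strand,
            transcripts=transcripts,
            principal_transcript_id=principal_id,
        )
    return genes


def guides_to_frame(guides: Sequence[GuideRecord]) -> pd.DataFrame:
    """Flatten GuideRecords (plus mRNA features) into a DataFrame."""
    rows = []
    for g in guides:
        row = {
            "guide_id": g.guide_id,
            "gene_id": g.gene_id,
            "spacer": g.spacer,
            "pam": g.pam,
            "contig": g.contig,
            "strand": g.guide_strand,
            "cut_coord": g.cut_coord,
            "aa1": g.aa1,
            "aa2": g.aa2,
            "offtarget_score": g.offtarget_score,
            "efficiency_score": g.efficiency_score,
        }
        for f in (
            "dist_5p_exon_border",
            "dist_3p_exon_border",
            "exon_length",
            "exon_multiple_of_3",
            "nmd_escape",
            "protein_fraction",
            "isoform_fraction",
            "same_strand_as_gene",
        ):
            row[f] = getattr(g.mrna, f)
        rows.append(row)
    return pd.DataFrame(rows)
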