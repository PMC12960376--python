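"""Transcript models: exon structure, CDS extent, and coordinate maps.

A :class:`TranscriptModel` is the package's view of one mRNA: ordered exons
(1-based inclusive genomic intervals, listed 5'→3' in transcript
orientation), the CDS extent, and the spliced sequences.  All downstream
modules (variant application, intron-retention modelling, NMD rules) speak
transcript-oriented coordinates only; strand handling ends here.

Models are loaded from GenBank flat files or GFF3+FASTA pairs.  Validation
is strict: the CDS must be a positive multiple of 3, end in a stop codon,
contain no internal stop and no ambiguity codes — in-silico translation has
to be deterministic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "TranscriptModel",
    "load_transcript",
    "map_cds_to_mrna",
    "map_mrna_to_cds",
    "exon_index_of",
    "intron_seq",
    "TranscriptNotFoundError",
    "MalformedCdsError",
    "CoordinateError",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


class TranscriptNotFoundError(KeyError):
    """Requested transcript is not present in the annotation source."""


class MalformedCdsError(ValueError):
    """CDS fails structural validation (length, stops, ambiguity codes)."""


class CoordinateError(IndexError):
    """A transcript/CDS coordinate is out of bounds."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: exons, CDS extent, and sequences.

    ``exons`` are genomic intervals, 1-based inclusive, ordered 5'→3' in
    transcript orientation (for strand '-' the first exon has the largest
    genomic coordinates).  ``mrna_seq``/``cds_seq`` are transcript-oriented.
    """

    transcript_id: str
    gene_symbol: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_genomic_start: int
    cds_genomic_end: int
    mrna_seq: str
    cds_seq: str
    utr5_len: int
    genomic_seq: str | None = None
    protein_id: str | None = None
    _exon_cum_ends: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        lens = [e - s + 1 for s, e in self.exons]
        if any(l <= 0 for l in lens):
            raise ValueError("exon end precedes start")
        # non-overlap in genomic space
        ivs = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError("overlapping exons")
        cum, tot = [], 0
        for l in lens:
            tot += l
            cum.append(tot)
        object.__setattr__(self, "_exon_cum_ends", tuple(cum))
        if tot != len(self.mrna_seq):
            raise ValueError("exon lengths do not sum to mRNA length")
        if self.mrna_seq[self.utr5_len:self.utr5_len + len(self.cds_seq)] != self.cds_seq:
            raise ValueError("CDS is not a contiguous substring of the mRNA")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_mrna_ends(self) -> tuple[int, ...]:
        """Cumulative 1-based mRNA position of the last base of each exon."""
        return self._exon_cum_ends

    def validate_cds(self) -> None:
        """Check CDS shape for a complete coding record.

        Raises :class:`MalformedCdsError` on: length not a positive multiple
        of 3, ambiguity codes, missing terminal stop, or a premature stop.
        """
        cds = self.cds_seq
        if len(cds) == 0 or len(cds) % 3:
            raise MalformedCdsError("malformed CDS")
        if set(cds) - set("ACGT"):
            raise MalformedCdsError("malformed CDS: ambiguous base in CDS")
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        if codons[-1] not in STOP_CODONS:
            raise MalformedCdsError("malformed CDS: no terminal stop codon")
        if any(c in STOP_CODONS for c in codons[:-1]):
            raise MalformedCdsError("premature stop in reference")

    def protein_seq(self) -> str:
        """Translation of the CDS, stop excluded (standard genetic code)."""
        return str(Seq(self.cds_seq[:-3]).translate())


def map_cds_to_mrna(t: TranscriptModel, cds_pos: int) -> int:
    """1-based spliced-mRNA position of CDS base ``cds_pos``.

    Strictly increasing in ``cds_pos``; the CDS occupies a contiguous mRNA
    interval starting right after the 5'UTR.
    """
    if not 1 <= cds_pos <= len(t.cds_seq):
        raise CoordinateError("coordinate out of bounds")
    return t.utr5_len + cds_pos


def map_mrna_to_cds(t: TranscriptModel, mrna_pos: int) -> int:
    """Inverse of :func:`map_cds_to_mrna`."""
    cds_pos = mrna_pos - t.utr5_len
    if not 1 <= cds_pos <= len(t.cds_seq):
        raise CoordinateError("coordinate out of bounds")
    return cds_pos


def exon_index_of(t: TranscriptModel, mrna_pos: int) -> tuple[int, int]:
    """Return (1-based exon index, distance to that exon's last mRNA base)."""
    if not 1 <= mrna_pos <= len(t.mrna_seq):
        raise CoordinateError("coordinate out of bounds")
    for idx, end in enumerate(t.exon_mrna_ends, start=1):
        if mrna_pos <= end:
            return idx, end - mrna_pos
    raise CoordinateError("coordinate out of bounds")  # pragma: no cover


def intron_seq(t: TranscriptModel, intron_index: int) -> str:
    """Transcript-oriented sequence of the intron after exon ``intron_index``.

    Requires ``genomic_seq``.  ``intron_index`` is 1-based; intron *i* lies
    between exons *i* and *i+1* in transcript order.
    """
    if t.genomic_seq is None:
        raise ValueError("genomic sequence required")
    if not 1 <= intron_index <= t.n_exons - 1:
        raise CoordinateError("coordinate out of bounds")
    up, down = t.exons[intron_index - 1], t.exons[intron_index]
    if t.strand == "+":
        seq = t.genomic_seq[up[1]:down[0] - 1]
    else:
        seq = str(Seq(t.genomic_seq[down[1]:up[0] - 1]).reverse_complement())
    return seq


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_transcript(source, transcript_id: str) -> TranscriptModel:
    """Load and validate one transcript from an annotation source.

    Parameters
    ----------
    source
        Path to a GenBank flat file, or a ``(gff3_path, fasta_path)`` pair.
    transcript_id
        ID to select (GenBank ``/transcript_id`` or a record whose mRNA/CDS
        features carry it; GFF3 transcript feature ID).

    The returned model is validated: CDS a multiple of 3 ending in a stop
    with no internal stop, and — when the record annotates a protein
    product — the CDS translation must match it.
    """
    if isinstance(source, (tuple, list)):
        t = _load_from_gff3(source[0], source[1], transcript_id)
    else:
        t = _load_from_genbank(source, transcript_id)
    t.validate_cds()
    return t


def _feature_qual(feat, key):
    vals = feat.qualifiers.get(key)
    return vals[0] if vals else None


def _exons_from_location(loc, strand: str) -> tuple[tuple[int, int], ...]:
    parts = [(int(p.start) + 1, int(p.end)) for p in loc.parts]
    parts.sort(reverse=(strand == "-"))
    return tuple(parts)


def _load_from_genbank(path, transcript_id: str) -> TranscriptModel:
    for record in SeqIO.parse(os.fspath(path), "genbank"):
        mrna = cds = None
        for feat in record.features:
            if _feature_qual(feat, "transcript_id") == transcript_id or (
                feat.type in ("mRNA", "CDS") and record.id == transcript_id
            ):
                if feat.type == "mRNA":
                    mrna = feat
                elif feat.type == "CDS":
                    cds = feat
        if cds is None:
            continue
        genomic = str(record.seq).upper()
        strand = "-" if (cds.location.strand or 1) < 0 else "+"
        if mrna is not None:
            exons = _exons_from_location(mrna.location, strand)
        else:  # CDS-only record: treat CDS parts as the exon structure
            exons = _exons_from_location(cds.location, strand)
        cds_parts = sorted(
            ((int(p.start) + 1, int(p.end)) for p in cds.location.parts),
            reverse=(strand == "-"),
        )
        mrna_seq = _splice(genomic, exons, strand)
        cds_seq = _splice(genomic, tuple(cds_parts), strand)
        pos = mrna_seq.find(cds_seq)
        if pos < 0:
            raise MalformedCdsError("malformed CDS: CDS not contained in mRNA")
        gene = None
        for feat in record.features:
            if feat.type == "gene":
                gene = _feature_qual(feat, "gene")
        t = TranscriptModel(
            transcript_id=transcript_id,
            gene_symbol=gene or _feature_qual(cds, "gene") or "",
            strand=strand,
            exons=exons,
            cds_genomic_start=cds_parts[0][0] if strand == "+" else cds_parts[0][1],
            cds_genomic_end=cds_parts[-1][1] if strand == "+" else cds_parts[-1][0],
            mrna_seq=mrna_seq,
            cds_seq=cds_seq,
            utr5_len=pos,
            genomic_seq=genomic,
            protein_id=_feature_qual(cds, "protein_id"),
        )
        annotated = _feature_qual(cds, "translation")
        if annotated is not None and t.protein_seq() != annotated:
            raise MalformedCdsError("malformed CDS: translation mismatch with annotated product")
        return t
    raise TranscriptNotFoundError(f"transcript {transcript_id!r} not found")


def _splice(genomic: str, parts: Sequence[tuple[int, int]], strand: str) -> str:
    chunks = []
    for s, e in parts:
        chunk = genomic[s - 1:e]
        if strand == "-":
            chunk = str(Seq(chunk).reverse_complement())
        chunks.append(chunk)
    return "".join(chunks)


def _load_from_gff3(gff_path, fasta_path, transcript_id: str) -> TranscriptModel:
    import gffutils

    db = gffutils.create_db(
        os.fspath(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    try:
        tr = db[transcript_id]
    except gffutils.exceptions.FeatureNotFoundError as exc:
        raise TranscriptNotFoundError(f"transcript {transcript_id!r} not found") from exc
    strand = tr.strand if tr.strand in "+-" else "+"
    exon_feats = list(db.children(tr, featuretype="exon"))
    cds_feats = list(db.children(tr, featuretype="CDS"))
    if not cds_feats:
        raise MalformedCdsError("malformed CDS: no CDS feature annotated")
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(fasta_path), "fasta")}
    if tr.seqid not in seqs:
        raise TranscriptNotFoundError(f"sequence {tr.seqid!r} not found in FASTA")
    genomic = seqs[tr.seqid]
    exons = tuple(sorted(((f.start, f.end) for f in exon_feats), reverse=(strand == "-")))
    cds_parts = tuple(sorted(((f.start, f.end) for f in cds_feats), reverse=(strand == "-")))
    mrna_seq = _splice(genomic, exons, strand)
    cds_seq = _splice(genomic, cds_parts, strand)
    pos = mrna_seq.find(cds_seq)
    if pos < 0:
        raise MalformedCdsError("malformed CDS: CDS not contained in mRNA")
    gene = tr.attributes.get("gene_name", [None])[0] or tr.attributes.get("gene", [""])[0]
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_symbol=gene or "",
        strand=strand,
        exons=exons,
        cds_genomic_start=cds_parts[0][0] if strand == "+" else cds_parts[0][1],
        cds_genomic_end=cds_parts[-1][1] if strand == "+" else cds_parts[-1][0],
        mrna_seq=mrna_seq,
        cds_seq=cds_seq,
        utr5_len=pos,
        genomic_seq=genomic,
    )
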