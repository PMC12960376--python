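"""HGVS c. variant application, in-silico translation, and consequences.

The supported HGVS subset is the one needed for coding single-nucleotide
variants, small deletions/duplications/delins, and splice-donor intronic
substitutions (``c.4953+1G>A`` style).  Variants are applied directly to the
wild-type CDS (in descending coordinate order so earlier coordinates stay
valid, which also makes cis-compound application well defined), the mutant
CDS is translated with the standard genetic code, and the protein-level
consequence (class, p. notation, predicted length, AA%) is derived by
diffing mutant against wild-type protein.

AA% — the truncation metric — is the predicted variant protein length as a
percentage of the wild-type length (2261 residues for the CaV2.1 α1A
subunit), rounded half-up to one decimal for display; statistics elsewhere
in the package use the unrounded fraction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from Bio.Seq import Seq

from .gene_models import TranscriptModel, exon_index_of, intron_seq, map_cds_to_mrna

__all__ = [
    "CdnaVariant",
    "ProteinConsequence",
    "parse_cdna_variant",
    "apply_variants",
    "translate_cds",
    "model_intron_retention",
    "protein_consequence",
    "predicted_length_from_p_notation",
    "aa_percent",
    "HgvsParseError",
    "UnsupportedVariantError",
    "ReferenceMismatchError",
    "ConflictingVariantsError",
    "AmbiguousBaseError",
]

WILDTYPE_LENGTH = 2261  # CaV2.1 α1A reference isoform, residues


class HgvsParseError(ValueError):
    """Malformed HGVS description."""


class UnsupportedVariantError(ValueError):
    """Syntactically valid HGVS outside the supported subset."""


class ReferenceMismatchError(ValueError):
    """Stated reference allele disagrees with the CDS."""


class ConflictingVariantsError(ValueError):
    """Two cis variants overlap."""


class AmbiguousBaseError(ValueError):
    """Non-ACGT character where a determinate base is required."""


@dataclass(frozen=True)
class CdnaVariant:
    """A parsed HGVS c. description (CDS coordinates, 1-based inclusive)."""

    raw: str
    kind: str  # substitution | deletion | duplication | delins | intronic_substitution
    cds_start: int
    cds_end: int
    intron_offset: int | None = None
    ref_allele: str = ""
    alt_allele: str = ""

    def __post_init__(self) -> None:
        if self.cds_start > self.cds_end:
            raise HgvsParseError("parse error: start exceeds end")
        if (self.intron_offset is not None) != (self.kind == "intronic_substitution"):
            raise HgvsParseError("parse error: intron offset inconsistent with kind")

    @property
    def net_length_change(self) -> int:
        if self.kind == "substitution":
            return 0
        if self.kind == "deletion":
            return -(self.cds_end - self.cds_start + 1)
        if self.kind == "duplication":
            return self.cds_end - self.cds_start + 1
        if self.kind == "delins":
            return len(self.alt_allele) - (self.cds_end - self.cds_start + 1)
        return 0


@dataclass(frozen=True)
class ProteinConsequence:
    """Predicted protein-level outcome of one (or one cis set of) variant(s)."""

    p_notation: str
    consequence_class: str
    variant_protein: str
    predicted_length: int
    wildtype_length: int
    terminated: bool = True

    def __post_init__(self) -> None:
        if self.predicted_length != len(self.variant_protein):
            raise ValueError("predicted_length inconsistent with variant_protein")

    @property
    def aa_fraction(self) -> float:
        """Unrounded length fraction; the statistics-facing value."""
        return self.predicted_length / self.wildtype_length

    @property
    def aa_percent(self) -> float:
        """Display AA%: 100 x fraction, rounded half-up to 1 decimal."""
        return aa_percent(self.predicted_length, self.wildtype_length)

    @property
    def has_ptc(self) -> bool:
        return self.consequence_class in (
            "stopgain",
            "frameshift",
            "splice_intron_retention",
        ) and self.terminated


def aa_percent(predicted_length: int, wildtype_length: int) -> float:
    """100 x predicted/wild-type length, rounded half-up to 1 decimal.

    Half-up (not banker's) rounding so 2260/2261 -> 100.0 as printed for
    in-frame single-residue deletions.
    """
    frac = Decimal(100 * predicted_length) / Decimal(wildtype_length)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_SUB = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_INTRONIC = re.compile(r"^c\.(\d+)([+-])(\d+)([ACGT])>([ACGT])$")
_DEL = re.compile(r"^c\.(\d+)(?:_(\d+))?del([ACGT]+)?$")
_DUP = re.compile(r"^c\.(\d+)(?:_(\d+))?dup([ACGT]+)?$")
_DELINS = re.compile(r"^c\.(\d+)(?:_(\d+))?delins([ACGT]+)$")
_UNSUPPORTED = re.compile(r"inv|ext|ins(?!$)|\[|\(|=|\?")


def parse_cdna_variant(hgvs: str) -> CdnaVariant:
    """Parse one HGVS c. string from the supported subset.

    Supported: ``c.NNNR>A`` substitutions, ``c.N[_M]del[SEQ]`` deletions,
    ``c.N[_M]dup`` duplications, ``c.N_MdelinsSEQ``, and intronic
    substitutions ``c.N+kR>A`` / ``c.N-kR>A``.
    """
    hgvs = hgvs.strip().replace(" ", "")
    if not hgvs.startswith("c."):
        raise HgvsParseError("parse error: missing 'c.' prefix")
    m = _SUB.match(hgvs)
    if m:
        pos = int(m.group(1))
        return CdnaVariant(hgvs, "substitution", pos, pos,
                           ref_allele=m.group(2), alt_allele=m.group(3))
    m = _INTRONIC.match(hgvs)
    if m:
        pos = int(m.group(1))
        offset = int(m.group(3)) * (1 if m.group(2) == "+" else -1)
        return CdnaVariant(hgvs, "intronic_substitution", pos, pos,
                           intron_offset=offset,
                           ref_allele=m.group(4), alt_allele=m.group(5))
    m = _DELINS.match(hgvs)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        return CdnaVariant(hgvs, "delins", start, end, alt_allele=m.group(3))
    m = _DEL.match(hgvs)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        ref = m.group(3) or ""
        if ref and len(ref) != end - start + 1:
            raise HgvsParseError("parse error: deleted sequence length mismatch")
        return CdnaVariant(hgvs, "deletion", start, end, ref_allele=ref)
    m = _DUP.match(hgvs)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        return CdnaVariant(hgvs, "duplication", start, end, ref_allele=m.group(3) or "")
    if _UNSUPPORTED.search(hgvs):
        raise UnsupportedVariantError("unsupported variant syntax")
    raise HgvsParseError("parse error")


# ---------------------------------------------------------------------------
# Application & translation
# ---------------------------------------------------------------------------

def apply_variants(cds: str, variants: list[CdnaVariant]) -> str:
    """Apply coding variants (singly or in cis) to a CDS string.

    Variants are applied in descending coordinate order so that indels do
    not invalidate the coordinates of variants 5' of them; a cis compound
    is therefore a single well-defined edit of one CDS copy.
    """
    for v in variants:
        if v.kind == "intronic_substitution":
            raise UnsupportedVariantError("requires intron retention modeling")
        if not 1 <= v.cds_start <= v.cds_end <= len(cds):
            raise HgvsParseError("coordinate out of bounds")
    ordered = sorted(variants, key=lambda v: v.cds_start, reverse=True)
    for a, b in zip(ordered, ordered[1:]):
        if b.cds_end >= a.cds_start:
            raise ConflictingVariantsError("conflicting variants")
    seq = cds
    for v in ordered:
        ref = seq[v.cds_start - 1:v.cds_end]
        if v.ref_allele and ref != v.ref_allele:
            raise ReferenceMismatchError(
                f"reference allele mismatch at c.{v.cds_start}: "
                f"expected {v.ref_allele}, found {ref}"
            )
        if v.kind == "substitution":
            seq = seq[:v.cds_start - 1] + v.alt_allele + seq[v.cds_end:]
        elif v.kind == "deletion":
            seq = seq[:v.cds_start - 1] + seq[v.cds_end:]
        elif v.kind == "duplication":
            seq = seq[:v.cds_end] + ref + seq[v.cds_end:]
        elif v.kind == "delins":
            seq = seq[:v.cds_start - 1] + v.alt_allele + seq[v.cds_end:]
        else:  # pragma: no cover
            raise UnsupportedVariantError("unsupported variant syntax")
    return seq


def translate_cds(nt: str) -> tuple[str, bool]:
    """Translate from position 1, standard code, stopping at the first stop.

    Returns ``(protein, terminated)``; the stop is excluded from the
    protein.  A trailing partial codon is ignored.  ``terminated`` is False
    when no stop codon is reached before the sequence ends.
    """
    if len(nt) < 3:
        raise ValueError("sequence shorter than one codon")
    if set(nt) - set("ACGT"):
        raise AmbiguousBaseError("ambiguous base")
    usable = len(nt) - len(nt) % 3
    aa = str(Seq(nt[:usable]).translate())
    stop = aa.find("*")
    if stop >= 0:
        return aa[:stop], True
    return aa, False


def model_intron_retention(t: TranscriptModel, v: CdnaVariant) -> str:
    """Mutant coding mRNA under donor-site intron retention.

    For a splice-donor substitution (offset +1/+2 past the last base of an
    exon), the modelled transcript keeps the downstream intron: the output
    is the CDS prefix through that exon's last coding base concatenated
    with the intron sequence carrying the variant base.  Translation of the
    result runs into the retained intron until its first in-frame stop
    (or off the end if none, flagged downstream as no_stop_found).
    """
    if v.kind != "intronic_substitution":
        raise UnsupportedVariantError("unsupported variant syntax")
    if v.intron_offset is None or v.intron_offset not in (1, 2):
        raise UnsupportedVariantError(
            "unsupported variant syntax: only donor +1/+2 retention is modeled"
        )
    if t.genomic_seq is None:
        raise ValueError("genomic sequence required")
    anchor_mrna = map_cds_to_mrna(t, v.cds_start)
    exon_idx, dist = exon_index_of(t, anchor_mrna)
    if dist != 0 or exon_idx >= t.n_exons:
        raise ValueError("anchor position is not a donor-site exon end")
    intron = intron_seq(t, exon_idx)
    k = v.intron_offset
    if k > len(intron):
        raise ValueError("coordinate outside intron")
    if v.ref_allele and intron[k - 1] != v.ref_allele:
        raise ReferenceMismatchError(
            f"reference allele mismatch at c.{v.cds_start}+{k}: "
            f"expected {v.ref_allele}, found {intron[k - 1]}"
        )
    mutated_intron = intron[:k - 1] + v.alt_allele + intron[k:]
    return t.cds_seq[:v.cds_start] + mutated_intron


# ---------------------------------------------------------------------------
# Consequence classification
# ---------------------------------------------------------------------------

def _first_mismatch(a: str, b: str) -> int:
    """0-based index of the first differing position (over the shorter)."""
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return i
    return min(len(a), len(b))


def protein_consequence(
    wt_protein: str,
    variant_protein: str,
    terminated: bool = True,
    *,
    splice: bool = False,
) -> ProteinConsequence:
    """Classify a variant protein against wild-type by sequence diff.

    Classification: identical → synonymous; equal length with interior
    substitution(s) → missense; clean truncation → stopgain (p.Xpos*);
    gapped prefix+suffix match → in-frame deletion/insertion; diverging
    novel tail ending in a stop → frameshift ``p.XposYfs*N`` with
    ``N = predicted_length − pos + 2`` (the stop is codon N of the new
    frame, the first changed residue codon 1).  A truncated protein whose
    tail still matches wild-type in frame (a cis missense + stopgain
    compound) is classified as stopgain.  ``splice=True`` marks an
    intron-retention product (p. notation "unknown", per-variant class
    splice_intron_retention) — the length/AA% machinery is shared.
    """
    if not wt_protein or not variant_protein:
        raise ValueError("empty sequence")
    wt, var = wt_protein, variant_protein
    n_wt, n_var = len(wt), len(var)

    def make(p_notation, klass):
        return ProteinConsequence(
            p_notation=p_notation,
            consequence_class=klass,
            variant_protein=var,
            predicted_length=n_var,
            wildtype_length=n_wt,
            terminated=terminated,
        )

    if splice:
        return make("unknown", "splice_intron_retention")
    if var == wt:
        return make("p.(=)", "synonymous")

    p0 = _first_mismatch(wt, var)  # 0-based
    pos = p0 + 1

    if not terminated:
        if n_var > p0:
            return make(f"p.{wt[p0] if p0 < n_wt else '*'}{pos}{var[p0]}fs*?", "no_stop_found")
        return make("p.*?", "no_stop_found")

    if n_var == n_wt:
        mismatches = [i for i, (x, y) in enumerate(zip(wt, var)) if x != y]
        if len(mismatches) == 1:
            i = mismatches[0]
            return make(f"p.{wt[i]}{i + 1}{var[i]}", "missense")
        parts = ";".join(f"{wt[i]}{i + 1}{var[i]}" for i in mismatches)
        return make(f"p.[{parts}]", "missense")

    if n_var < n_wt:
        if var == wt[:n_var]:
            # pure truncation: next wild-type residue replaced by a stop
            return make(f"p.{wt[n_var]}{n_var + 1}*", "stopgain")
        # gapped match: in-frame deletion (prefix + suffix cover the variant)
        d = n_wt - n_var
        suf = _common_suffix_len(wt, var, limit=n_var - p0)
        if p0 + suf >= n_var:
            start0 = n_var - suf  # deletion of wt[start0 : start0+d], 0-based
            start0, end0 = _shift_deletion_3prime(wt, start0, d)
            if d == 1:
                note = f"p.{wt[start0]}{start0 + 1}del"
            else:
                note = f"p.{wt[start0]}{start0 + 1}_{wt[end0]}{end0 + 1}del"
            return make(note, "inframe_deletion")
        # frameshift unless the tail realigns in frame (missense+stopgain cis)
        tail = min(5, n_var - p0 - 1)
        if tail > 0 and var[-tail:] == wt[n_var - tail:n_var]:
            return make(f"p.{wt[n_var]}{n_var + 1}*", "stopgain")
        return make(f"p.{wt[p0]}{pos}{var[p0]}fs*{n_var - pos + 2}", "frameshift")

    # longer than wild-type
    d = n_var - n_wt
    suf = _common_suffix_len(wt, var, limit=n_wt - p0)
    if p0 + suf >= n_wt:
        ins = var[p0:p0 + d]
        left = f"{wt[p0 - 1]}{p0}" if p0 >= 1 else "?0"
        right = f"{wt[p0]}{p0 + 1}" if p0 < n_wt else "*"
        if p0 >= d and wt[p0 - d:p0] == ins:
            note = (f"p.{wt[p0 - 1]}{p0}dup" if d == 1
                    else f"p.{wt[p0 - d]}{p0 - d + 1}_{wt[p0 - 1]}{p0}dup")
        else:
            note = f"p.{left}_{right}ins{ins}"
        return make(note, "inframe_insertion")
    return make(f"p.{wt[p0]}{pos}{var[p0]}fs*{n_var - pos + 2}", "frameshift")


def _common_suffix_len(a: str, b: str, limit: int) -> int:
    n = 0
    while n < limit and n < len(a) and n < len(b) and a[-1 - n] == b[-1 - n]:
        n += 1
    return n


def _shift_deletion_3prime(wt: str, start0: int, d: int) -> tuple[int, int]:
    """3'-most equivalent placement of a deletion (HGVS normalization)."""
    while start0 + d < len(wt) and wt[start0] == wt[start0 + d]:
        start0 += 1
    return start0, start0 + d - 1


# ---------------------------------------------------------------------------
# p. notation arithmetic (validation shortcut; also the no-structure path)
# ---------------------------------------------------------------------------

_P_STOPGAIN = re.compile(r"^p\.[A-Z](\d+)\*$")
_P_FRAMESHIFT = re.compile(r"^p\.[A-Z](\d+)[A-Z]fs\*(\d+)$")
_P_MISSENSE = re.compile(r"^p\.[A-Z](\d+)[A-Z]$")
_P_DEL1 = re.compile(r"^p\.[A-Z](\d+)del$")
_P_DELRANGE = re.compile(r"^p\.[A-Z](\d+)_[A-Z](\d+)del$")


def predicted_length_from_p_notation(p: str, wildtype_length: int) -> int:
    """Predicted protein length (stop excluded) implied by a p. notation.

    stopgain ``p.Xpos*`` → pos−1; frameshift ``p.XposYfs*N`` → pos+N−2
    (the stop is codon N of the shifted frame); missense → wild-type
    length; deletions → wild-type length minus deleted span.
    """
    p = p.strip().replace(" ", "")
    m = _P_STOPGAIN.match(p)
    if m:
        return int(m.group(1)) - 1
    m = _P_FRAMESHIFT.match(p)
    if m:
        return int(m.group(1)) + int(m.group(2)) - 2
    m = _P_MISSENSE.match(p)
    if m:
        return wildtype_length
    m = _P_DEL1.match(p)
    if m:
        return wildtype_length - 1
    m = _P_DELRANGE.match(p)
    if m:
        return wildtype_length - (int(m.group(2)) - int(m.group(1)) + 1)
    if p == "p.(=)":
        return wildtype_length
    raise UnsupportedVariantError("unsupported p. syntax")
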