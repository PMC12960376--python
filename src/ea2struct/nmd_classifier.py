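"""Nonsense-mediated decay (NMD) prediction for premature stops.

A premature termination codon (PTC) normally targets the transcript for
NMD; four canonical escape rules (the ones the Ensembl VEP NMD plugin
encodes) exempt it:

1. intronless transcript;
2. PTC in the last exon;
3. PTC within 50 nt upstream of the last exon-exon junction (i.e. in the
   final 50 bases of the penultimate exon), boundary inclusive;
4. PTC within the first 100 coding bases, boundary inclusive.

If any rule fires the verdict is "unlikely" (to undergo NMD); otherwise
"likely".  Missense/in-frame consequences carry no PTC and are reported as
"unlikely" with escape_rule "not_applicable".

PTC coordinates are evaluated on the *variant* transcript: exon junction
positions are shifted by the net indel length of any upstream coding edit,
and a retained intron merges its two flanking exons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .gene_models import TranscriptModel
from .variant_engine import CdnaVariant, ProteinConsequence

__all__ = ["NmdCall", "classify_nmd", "NoPtcError"]

JUNCTION_RULE_NT = 50
START_PROXIMAL_NT = 100


class NoPtcError(ValueError):
    """Consequence has no resolvable premature termination codon."""


@dataclass(frozen=True)
class NmdCall:
    verdict: str  # "likely" | "unlikely"
    escape_rule: str  # last_exon | near_penultimate_junction | first_100_coding
    #                 | intronless | none | not_applicable
    ptc_cds_pos: int | None
    ptc_mrna_pos: int | None
    ptc_exon_index: int | None

    def __post_init__(self) -> None:
        if self.verdict not in ("likely", "unlikely"):
            raise ValueError(f"invalid verdict {self.verdict!r}")
        if (self.verdict == "likely") != (self.escape_rule == "none"):
            raise ValueError("verdict inconsistent with escape rule")


def _variant_exon_ends(
    t: TranscriptModel,
    variants: Sequence[CdnaVariant],
    retained_intron: tuple[int, int] | None,
) -> list[int]:
    """Cumulative mRNA end positions of each exon on the variant transcript."""
    ends = list(t.exon_mrna_ends)
    for v in variants:
        if v.kind == "intronic_substitution":
            continue
        d = v.net_length_change
        if d == 0:
            continue
        edit_mrna = t.utr5_len + v.cds_start
        ends = [e + d if e >= edit_mrna else e for e in ends]
    if retained_intron is not None:
        # the retained intron merges exons i and i+1 into one
        i, L = retained_intron
        ends = ends[:i - 1] + [e + L for e in ends[i:]]
    return ends


def classify_nmd(
    t: TranscriptModel,
    consequence: ProteinConsequence,
    variants: Sequence[CdnaVariant] = (),
) -> NmdCall:
    """Apply the NMD escape rules to the PTC implied by ``consequence``.

    ``variants`` (optional) are the applied cDNA changes; they refine the
    exon-junction positions on the variant transcript for indels and
    identify the retained intron for splice consequences.
    """
    if consequence.consequence_class in (
        "synonymous", "missense", "inframe_deletion", "inframe_insertion",
    ):
        return NmdCall("unlikely", "not_applicable", None, None, None)
    if not consequence.terminated:
        raise NoPtcError("no PTC")
    if not consequence.has_ptc:
        raise NoPtcError("no PTC")

    retained = None
    if consequence.consequence_class == "splice_intron_retention":
        donor = next((v for v in variants if v.kind == "intronic_substitution"), None)
        if donor is None:
            raise NoPtcError("no PTC: retained intron not identified")
        anchor_mrna = t.utr5_len + donor.cds_start
        exon_idx = next(
            i for i, e in enumerate(t.exon_mrna_ends, start=1) if anchor_mrna <= e
        )
        # transcript-order intron length, independent of strand
        up, down = t.exons[exon_idx - 1], t.exons[exon_idx]
        intron_len = (down[0] - up[1] - 1) if t.strand == "+" else (up[0] - down[1] - 1)
        retained = (exon_idx, intron_len)

    ends = _variant_exon_ends(t, variants, retained)
    n_exons = len(ends)

    # first base of the new stop codon, variant-CDS coordinates
    ptc_cds = 3 * consequence.predicted_length + 1
    ptc_mrna = t.utr5_len + ptc_cds
    if ptc_mrna > ends[-1]:
        raise NoPtcError("no PTC: stop position beyond variant transcript")
    ptc_exon = next(i for i, e in enumerate(ends, start=1) if ptc_mrna <= e)

    if n_exons == 1:
        rule = "intronless"
    elif ptc_mrna > ends[-2]:
        rule = "last_exon"
    elif ends[-2] - ptc_mrna <= JUNCTION_RULE_NT:
        rule = "near_penultimate_junction"
    elif ptc_cds <= START_PROXIMAL_NT:
        rule = "first_100_coding"
    else:
        rule = "none"

    verdict = "likely" if rule == "none" else "unlikely"
    return NmdCall(verdict, rule, ptc_cds, ptc_mrna, ptc_exon)
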