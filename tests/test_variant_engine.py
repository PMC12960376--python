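"""HGVS parsing, variant application, translation, and consequence calls."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ea2struct import (
    aa_percent,
    apply_variants,
    model_intron_retention,
    parse_cdna_variant,
    predicted_length_from_p_notation,
    protein_consequence,
    translate_cds,
)
from ea2struct.variant_engine import (
    AmbiguousBaseError,
    ConflictingVariantsError,
    HgvsParseError,
    ReferenceMismatchError,
    UnsupportedVariantError,
)

# independent codon table for the translation oracle
_ORACLE_TABLE = {}
for i, b1 in enumerate("TCAG"):
    for j, b2 in enumerate("TCAG"):
        for k, b3 in enumerate("TCAG"):
            _ORACLE_TABLE[b1 + b2 + b3] = (
                "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
            )[16 * i + 4 * j + k]


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("hgvs, kind, start, end, ref, alt, offset", [
    ("c.5569C>T", "substitution", 5569, 5569, "C", "T", None),
    ("c.2762C>G", "substitution", 2762, 2762, "C", "G", None),
    ("c.3414dup", "duplication", 3414, 3414, "", "", None),
    ("c.3871_3873delGAG", "deletion", 3871, 3873, "GAG", "", None),
    ("c.3679_3681delinsG", "delins", 3679, 3681, "", "G", None),
    ("c.4953+1G>A", "intronic_substitution", 4953, 4953, "G", "A", 1),
    ("c.100-2A>G", "intronic_substitution", 100, 100, "A", "G", -2),
])
def test_parse_supported_forms(hgvs, kind, start, end, ref, alt, offset):
    v = parse_cdna_variant(hgvs)
    assert (v.kind, v.cds_start, v.cds_end) == (kind, start, end)
    assert (v.ref_allele, v.alt_allele) == (ref, alt)
    assert v.intron_offset == offset


@pytest.mark.parametrize("hgvs, err", [
    ("c.76_77inv", UnsupportedVariantError),
    ("c.*110G>A", HgvsParseError),
    ("g.123A>T", HgvsParseError),
    ("c.12del34", HgvsParseError),
    ("c.10_12delAAAA", HgvsParseError),
])
def test_parse_rejects_unsupported_or_malformed(hgvs, err):
    with pytest.raises(err):
        parse_cdna_variant(hgvs)


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------

def test_apply_single_substitution():
    assert apply_variants("ATGGCTTGA", [parse_cdna_variant("c.4G>T")]) == "ATGTCTTGA"


def test_apply_deletion_shifts_downstream():
    out = apply_variants("ATGAAACCCTGA", [parse_cdna_variant("c.4_6delAAA")])
    assert out == "ATGCCCTGA"


def test_apply_duplication_copies_reference_base():
    assert apply_variants("ATGCAT", [parse_cdna_variant("c.5dup")]) == "ATGCAAT"


def test_reference_mismatch_raises():
    with pytest.raises(ReferenceMismatchError, match="reference allele mismatch"):
        apply_variants("ATGGCTTGA", [parse_cdna_variant("c.4A>T")])


def test_overlapping_variants_conflict():
    vs = [parse_cdna_variant("c.4_6delGCT"), parse_cdna_variant("c.5G>A")]
    with pytest.raises(ConflictingVariantsError):
        apply_variants("ATGGCTTGA", vs)


def test_intronic_variant_requires_retention_path():
    with pytest.raises(UnsupportedVariantError, match="intron retention"):
        apply_variants("ATGGCTTGA", [parse_cdna_variant("c.3+1G>A")])


@st.composite
def _cds_and_variants(draw):
    n = draw(st.integers(6, 40))
    cds = "".join(draw(st.lists(st.sampled_from("ACGT"), min_size=n, max_size=n)))
    k = draw(st.integers(1, 3))
    positions = draw(st.lists(st.integers(1, n), min_size=k, max_size=k, unique=True))
    variants = []
    for pos in positions:
        form = draw(st.sampled_from(["sub", "del", "dup"]))
        if form == "sub":
            alt = draw(st.sampled_from("ACGT"))
            variants.append(parse_cdna_variant(f"c.{pos}{cds[pos - 1]}>{alt}"))
        elif form == "del":
            variants.append(parse_cdna_variant(f"c.{pos}del"))
        else:
            variants.append(parse_cdna_variant(f"c.{pos}dup"))
    return cds, variants


@given(_cds_and_variants())
def test_cis_application_matches_segment_reconstruction(case):
    """Descending-order application equals an independent piecewise rebuild."""
    cds, variants = case
    starts = [v.cds_start for v in variants]
    ends = [v.cds_end for v in variants]
    if any(e >= s2 for (s2, e) in zip(sorted(starts)[1:], sorted(ends))):
        return  # overlapping draws are exercised by the conflict test
    # oracle: slice the CDS around each edit, ascending, tracking segments
    pieces, cursor = [], 0
    for v in sorted(variants, key=lambda v: v.cds_start):
        pieces.append(cds[cursor:v.cds_start - 1])
        ref = cds[v.cds_start - 1:v.cds_end]
        if v.kind == "substitution":
            pieces.append(v.alt_allele)
        elif v.kind == "deletion":
            pass
        elif v.kind == "duplication":
            pieces.append(ref + ref)
        cursor = v.cds_end
    pieces.append(cds[cursor:])
    expected = "".join(pieces)
    assert apply_variants(cds, variants) == expected


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("nt, prot, term", [
    ("ATGAAATAA", "MK", True),
    ("ATGAAA", "MK", False),
    ("ATGTGAAAA", "M", True),
])
def test_translate_examples(nt, prot, term):
    assert translate_cds(nt) == (prot, term)


def test_translate_matches_codon_table_oracle():
    rng = np.random.default_rng(11)
    nt = "".join(rng.choice(list("ACGT"), size=999))
    expected = []
    for i in range(0, 999, 3):
        aa = _ORACLE_TABLE[nt[i:i + 3]]
        if aa == "*":
            break
        expected.append(aa)
    prot, _ = translate_cds(nt)
    assert prot == "".join(expected)


def test_translate_rejects_ambiguous_base():
    with pytest.raises(AmbiguousBaseError, match="ambiguous base"):
        translate_cds("ATGNAA")


# ---------------------------------------------------------------------------
# intron retention
# ---------------------------------------------------------------------------

def test_intron_retention_matches_catalog_hand_translation(toy_gene):
    t, catalog = toy_gene
    for entry in catalog:
        if entry.expected_class != "splice_intron_retention":
            continue
        v = parse_cdna_variant(entry.hgvs_c)
        prot, term = translate_cds(model_intron_retention(t, v))
        assert term
        assert prot == entry.expected_protein
        assert len(prot) == entry.expected_length


def test_intron_retention_requires_genomic_sequence(toy_gene):
    import dataclasses

    t, _ = toy_gene
    bare = dataclasses.replace(t, genomic_seq=None)
    with pytest.raises(ValueError, match="genomic sequence required"):
        model_intron_retention(bare, parse_cdna_variant("c.250+1G>A"))


def test_intron_retention_rejects_non_donor_anchor(toy_gene):
    t, _ = toy_gene
    # cds 100 is not the last base of any exon
    with pytest.raises(ValueError, match="donor"):
        model_intron_retention(t, parse_cdna_variant("c.100+1G>A"))
    # a plain coding substitution is not a retention scenario at all
    with pytest.raises(UnsupportedVariantError):
        model_intron_retention(t, parse_cdna_variant("c.100A>G"))


# ---------------------------------------------------------------------------
# consequence classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("wt, var, term, p, klass", [
    ("MKTAY", "MKCAY", True, "p.T3C", "missense"),
    ("MKTAY", "MKTAY", True, "p.(=)", "synonymous"),
    ("MKTAYW", "MKT", True, "p.A4*", "stopgain"),
    ("MKTAY", "MKAY", True, "p.T3del", "inframe_deletion"),
    ("MKTAYQ", "MKWIL", True, "p.T3Wfs*4", "frameshift"),
])
def test_consequence_classification(wt, var, term, p, klass):
    c = protein_consequence(wt, var, term)
    assert c.p_notation == p
    assert c.consequence_class == klass
    assert c.predicted_length == len(var)


def test_consequence_compound_missense_plus_stopgain():
    # cis substitution upstream of a truncation: classified by the stop
    wt = "MKTAYWQRST"
    var = "MKCAYW"  # T3C plus stop after position 6
    c = protein_consequence(wt, var, True)
    assert c.consequence_class == "stopgain"
    assert c.p_notation == "p.Q7*"


def test_consequence_no_stop_flagged_not_raised():
    c = protein_consequence("MKTAY", "MKWILRRR", False)
    assert c.consequence_class == "no_stop_found"
    assert not c.terminated


def test_consequence_empty_sequence_raises():
    with pytest.raises(ValueError, match="empty sequence"):
        protein_consequence("", "MK", True)


@pytest.mark.parametrize("p, length, aa", [
    ("p.R1857*", 1856, 82.1),
    ("p.A1837Pfs*22", 1857, 82.1),
    ("p.H253Y", 2261, 100.0),
    ("p.K1139Qfs*6", 1143, 50.6),
    ("p.L1227Vfs*20", 1245, 55.1),
    ("p.R1819*", 1818, 80.4),
    ("p.E1291del", 2260, 100.0),
])
def test_predicted_length_from_notation_and_aa_percent(p, length, aa):
    """Length arithmetic of the fs*N / stopgain conventions on the study's
    own variants, and half-up AA% display rounding (2260/2261 -> 100.0)."""
    assert predicted_length_from_p_notation(p, 2261) == length
    assert aa_percent(length, 2261) == aa


def test_predicted_length_unsupported_syntax():
    with pytest.raises(UnsupportedVariantError, match="unsupported p. syntax"):
        predicted_length_from_p_notation("p.Met1ext-5", 2261)


def test_catalog_end_to_end_consistency(toy_gene):
    """c. -> protein -> p. -> length agrees with the independent catalog
    and with the p.-notation arithmetic, for every generated variant."""
    t, catalog = toy_gene
    wt = t.protein_seq()
    for entry in catalog:
        v = parse_cdna_variant(entry.hgvs_c)
        if v.kind == "intronic_substitution":
            prot, term = translate_cds(model_intron_retention(t, v))
            c = protein_consequence(wt, prot, term, splice=True)
        else:
            prot, term = translate_cds(apply_variants(t.cds_seq, [v]))
            c = protein_consequence(wt, prot, term)
        assert c.p_notation == entry.expected_p, entry.label
        assert c.predicted_length == entry.expected_length, entry.label
        assert c.aa_percent == entry.expected_aa_percent, entry.label
        if c.p_notation != "unknown":
            assert predicted_length_from_p_notation(
                c.p_notation, len(wt)) == c.predicted_length, entry.label


def test_aa_percent_class_bounds(toy_gene):
    t, catalog = toy_gene
    for entry in catalog:
        if entry.expected_class in ("stopgain", "frameshift"):
            assert entry.expected_aa_percent < 100.0
        if entry.expected_class == "missense":
            assert entry.expected_aa_percent == 100.0
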