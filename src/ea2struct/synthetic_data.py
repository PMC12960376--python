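"""Synthetic test-input generators with analytically known answers.

Three generators back the test suite (and the `simulate` CLI command):

* :func:`make_synthetic_gene` — a small multi-exon gene model plus a
  catalog of variants whose protein-level consequences (p. notation,
  length, AA%, NMD verdict) are derived here by independent arithmetic
  and plain codon-table translation, not by the variant engine under test.
* :func:`make_structure_pair` — wild-type/variant Cα models (jittered
  helical walks, ~3.8 Å spacing) whose TM-score is known exactly for
  noiseless truncations (= retained fraction) and bounded otherwise.
* :func:`simulate_cohort` — patient tables with family clustering and a
  known slope/correlation, for mixed-model parameter recovery.

Everything is deterministic per seed.  These fixtures emulate the *shapes*
of real inputs (RefSeq records, AlphaFold models, clinical tables), not
their biology: helical decoys carry no fold, pLDDT profiles are specified
rather than learned, and gene sequences are random codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from scipy.spatial.transform import Rotation

from .gene_models import TranscriptModel
from .structure_metrics import StructureModel
from .variant_engine import aa_percent

__all__ = [
    "SyntheticGeneSpec",
    "StructurePairSpec",
    "CohortSpec",
    "ExpectedConsequence",
    "make_synthetic_gene",
    "make_structure_pair",
    "simulate_cohort",
    "write_genbank",
]

# plain codon table, kept separate from Biopython so catalog expectations
# are derived independently of the translation path under test
_CODON = {}
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODON[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]

_SAFE_CODONS = [c for c, a in _CODON.items() if a != "*"]


def _simple_translate(nt: str) -> tuple[str, bool]:
    aa = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        a = _CODON[nt[i:i + 3]]
        if a == "*":
            return "".join(aa), True
        aa.append(a)
    return "".join(aa), False


@dataclass(frozen=True)
class ExpectedConsequence:
    """A catalog entry: one variant and its independently derived outcome."""

    hgvs_c: str
    expected_class: str
    expected_p: str
    expected_length: int
    expected_aa_percent: float
    expected_nmd: str | None  # "likely" / "unlikely" / None when no PTC rule applies
    expected_protein: str | None = None
    label: str = ""


@dataclass(frozen=True)
class SyntheticGeneSpec:
    """Layout of the toy gene.  Defaults give the 5-exon / 600-nt-CDS gene
    (199 residues + stop) used throughout the test suite."""

    n_exons: int = 5
    exon_lengths: tuple[int, ...] = (120, 180, 160, 150, 140)  # mRNA nt
    intron_lengths: tuple[int, ...] = (90, 93, 96, 90)
    utr5_length: int = 50
    seed: int = 7
    strand: str = "+"
    transcript_id: str = "TOY1.1"
    gene_symbol: str = "TOY1"

    def __post_init__(self) -> None:
        if len(self.exon_lengths) != self.n_exons:
            raise ValueError("invalid spec: exon count mismatch")
        if len(self.intron_lengths) != self.n_exons - 1:
            raise ValueError("invalid spec: need n_exons-1 introns")


CDS_LEN = 600  # fixed toy CDS: 200 codons = 199 residues + stop
_UTR3_LEN = 100

# designed codons (residue -> codon); chosen so each variant class has a
# hand-derivable outcome at a known transcript location
_DESIGNED = {
    20: "TAC",   # c.60C>A -> p.Y20* (PTC within first 100 coding bases)
    60: "CAT",   # c.178C>T -> p.H60Y missense
    80: "TAC",   # c.240C>A -> p.Y80* mid-transcript stopgain -> NMD likely
    100: "GAG",  # c.298_300delGAG -> p.E100del (neighbours forced different)
    101: "AAA",
    99: "AAA",
    117: "CAT",  # c.350dup duplicates the A -> CAA..., H117Qfs frameshift
    137: "TAC",  # exon 3 ends mid-codon after "TA": donor+1 gives immediate stop
    180: "TAC",  # c.540C>A -> p.Y180* within 50 nt of the last junction
    195: "TAC",  # c.585C>A -> p.Y195* in the last exon
}


def make_synthetic_gene(
    spec: SyntheticGeneSpec = SyntheticGeneSpec(),
) -> tuple[TranscriptModel, list[ExpectedConsequence]]:
    """Build the toy transcript model and its expected-consequence catalog."""
    if sum(spec.exon_lengths) != spec.utr5_length + CDS_LEN + _UTR3_LEN:
        raise ValueError("invalid spec: exon lengths incompatible with CDS frame")
    rng = np.random.default_rng(spec.seed)
    for _attempt in range(50):
        cds = _random_cds(rng)
        catalog, ok = _build_catalog(cds, spec)
        if ok:
            break
    else:  # pragma: no cover - seed-dependent safety net
        raise RuntimeError("could not realize a catalog-compatible CDS")
    t = _assemble_transcript(cds, spec, rng)
    # donor-site consequences need the realized introns
    catalog = catalog + _donor_catalog(t)
    return t, catalog


def _random_cds(rng) -> str:
    codons = ["ATG"]
    for r in range(2, 200):
        codons.append(_DESIGNED.get(r) or _SAFE_CODONS[rng.integers(len(_SAFE_CODONS))])
    codons.append("TAA")
    return "".join(codons)


def _exon_cds_ends(spec: SyntheticGeneSpec) -> list[int]:
    ends, tot = [], 0
    for l in spec.exon_lengths:
        tot += l
        ends.append(tot)
    return ends


def _build_catalog(cds: str, spec: SyntheticGeneSpec):
    """Coding-variant catalog with independently derived expectations."""
    wt_prot, _ = _simple_translate(cds)
    n_wt = len(wt_prot)
    ends = _exon_cds_ends(spec)  # mRNA cumulative exon ends
    utr5 = spec.utr5_length

    def nmd(ptc_cds, exon_ends=None):
        return _expected_nmd(utr5, exon_ends or ends, ptc_cds)

    cat = [
        ExpectedConsequence(
            "c.178C>T", "missense", "p.H60Y", n_wt, aa_percent(n_wt, n_wt),
            "unlikely", label="missense"),
        ExpectedConsequence(
            "c.240C>A", "stopgain", "p.Y80*", 79, aa_percent(79, n_wt),
            nmd(3 * 79 + 1), label="stopgain mid-transcript"),
        ExpectedConsequence(
            "c.60C>A", "stopgain", "p.Y20*", 19, aa_percent(19, n_wt),
            nmd(3 * 19 + 1), label="stopgain start-proximal"),
        ExpectedConsequence(
            "c.540C>A", "stopgain", "p.Y180*", 179, aa_percent(179, n_wt),
            nmd(3 * 179 + 1), label="stopgain near last junction"),
        ExpectedConsequence(
            "c.585C>A", "stopgain", "p.Y195*", 194, aa_percent(194, n_wt),
            nmd(3 * 194 + 1), label="stopgain in last exon"),
        ExpectedConsequence(
            "c.298_300delGAG", "inframe_deletion", "p.E100del", n_wt - 1,
            aa_percent(n_wt - 1, n_wt), "unlikely", label="in-frame deletion"),
    ]
    # frameshift duplication: expectation by direct string edit + translation
    dup_pos = 350
    edited = cds[:dup_pos] + cds[dup_pos - 1] + cds[dup_pos:]
    fs_prot, terminated = _simple_translate(edited)
    if not terminated:
        return cat, False  # re-draw the random codons
    p0 = next((i for i, (a, b) in enumerate(zip(wt_prot, fs_prot)) if a != b), None)
    if p0 is None:
        return cat, False
    n_fs = len(fs_prot)
    fs_ends = [e + 1 if e >= utr5 + dup_pos else e for e in ends]
    cat.append(ExpectedConsequence(
        f"c.{dup_pos}dup", "frameshift",
        f"p.{wt_prot[p0]}{p0 + 1}{fs_prot[p0]}fs*{n_fs - p0 + 1}",
        n_fs, aa_percent(n_fs, n_wt),
        _expected_nmd(utr5, fs_ends, 3 * n_fs + 1),
        expected_protein=fs_prot, label="frameshift duplication"))
    sane = p0 == 116 and n_fs < n_wt  # dup must shift frame at the designed codon
    return cat, sane


def _expected_nmd(utr5: int, exon_ends: list[int], ptc_cds: int) -> str:
    """Independent re-statement of the NMD escape rules for the catalog."""
    ptc_mrna = utr5 + ptc_cds
    if len(exon_ends) == 1:
        return "unlikely"
    if ptc_mrna > exon_ends[-2]:
        return "unlikely"  # last exon
    if exon_ends[-2] - ptc_mrna <= 50:
        return "unlikely"  # within 50 nt of the last junction
    if ptc_cds <= 100:
        return "unlikely"  # start-proximal
    return "likely"


def _assemble_transcript(cds: str, spec: SyntheticGeneSpec, rng) -> TranscriptModel:
    utr5 = "".join(rng.choice(list("ACGT"), size=spec.utr5_length))
    utr3 = "".join(rng.choice(list("ACGT"), size=_UTR3_LEN))
    mrna = utr5 + cds + utr3
    ends = _exon_cds_ends(spec)
    exon_seqs = [mrna[(0 if i == 0 else ends[i - 1]):ends[i]] for i in range(spec.n_exons)]

    introns = []
    for i, ilen in enumerate(spec.intron_lengths, start=1):
        cds_end_of_exon = ends[i - 1] - spec.utr5_length  # CDS pos of exon end
        introns.append(_design_intron(ilen, cds_end_of_exon, rng))

    genomic_parts, exons, pos = [], [], 1
    for i, ex in enumerate(exon_seqs):
        exons.append((pos, pos + len(ex) - 1))
        genomic_parts.append(ex)
        pos += len(ex)
        if i < len(introns):
            genomic_parts.append(introns[i])
            pos += len(introns[i])
    genomic = "".join(genomic_parts)

    if spec.strand == "-":
        n = len(genomic)
        genomic = str(Seq(genomic).reverse_complement())
        exons = [(n - e + 1, n - s + 1) for s, e in exons]

    cds_start_mrna = spec.utr5_length + 1
    cds_end_mrna = spec.utr5_length + len(cds)
    return TranscriptModel(
        transcript_id=spec.transcript_id,
        gene_symbol=spec.gene_symbol,
        strand=spec.strand,
        exons=tuple(exons),
        cds_genomic_start=_mrna_to_genomic(cds_start_mrna, exons, spec.strand),
        cds_genomic_end=_mrna_to_genomic(cds_end_mrna, exons, spec.strand),
        mrna_seq=mrna,
        cds_seq=cds,
        utr5_len=spec.utr5_length,
        genomic_seq=genomic,
    )


def _mrna_to_genomic(mrna_pos: int, exons, strand: str) -> int:
    off = mrna_pos
    for s, e in exons:
        l = e - s + 1
        if off <= l:
            return s + off - 1 if strand == "+" else e - off + 1
        off -= l
    raise ValueError("position beyond mRNA")


def _design_intron(length: int, cds_end_of_exon: int, rng) -> str:
    """GT...AG intron with a designed in-frame stop for donor+1 retention.

    The retained reading frame enters the intron after ``cds_end_of_exon``
    coding bases; a TAA is placed at the first in-frame boundary at least
    6 nt in, with stop-free 'C' filler elsewhere, so the donor+1 G>A
    product is hand-derivable.  A trailing base run keeps the requested
    length; internal sequence avoids in-frame stops by construction.
    """
    phase_fill = (-(cds_end_of_exon + 2 + 6)) % 3
    l1 = 6 + phase_fill  # 'C' filler before the stop, frame-aligned
    head = "GT" + "C" * l1 + "TAA"
    tail_len = length - len(head) - 2
    if tail_len < 0:
        raise ValueError("invalid spec: intron too short")
    tail = "".join(rng.choice(list("CT"), size=tail_len))  # CT-only: stop-free
    return head + tail + "AG"


def _donor_catalog(t: TranscriptModel) -> list[ExpectedConsequence]:
    """Donor+1 retention expectations, derived from the realized introns."""
    from .gene_models import intron_seq

    wt_prot, _ = _simple_translate(t.cds_seq)
    n_wt = len(wt_prot)
    out = []
    ends = list(t.exon_mrna_ends)
    for intron_idx in (2, 3):
        if intron_idx > t.n_exons - 1:
            continue
        e_cds = ends[intron_idx - 1] - t.utr5_len
        intron = intron_seq(t, intron_idx)
        mutated = "AT" + intron[2:]
        prot, terminated = _simple_translate(t.cds_seq[:e_cds] + mutated)
        assert terminated, "designed intron must contain an in-frame stop"
        up, down = t.exons[intron_idx - 1], t.exons[intron_idx]
        ilen = (down[0] - up[1] - 1) if t.strand == "+" else (up[0] - down[1] - 1)
        merged = ends[:intron_idx - 1] + [e + ilen for e in ends[intron_idx:]]
        out.append(ExpectedConsequence(
            f"c.{e_cds}+1G>A", "splice_intron_retention", "unknown",
            len(prot), aa_percent(len(prot), n_wt),
            _expected_nmd(t.utr5_len, merged, 3 * len(prot) + 1),
            expected_protein=prot,
            label=f"donor+1 retention of intron {intron_idx}"))
    return out


# ---------------------------------------------------------------------------
# GenBank round-trip
# ---------------------------------------------------------------------------

def write_genbank(t: TranscriptModel, path) -> None:
    """Write a transcript model as a GenBank flat file (gene/mRNA/CDS joins)."""
    record = SeqRecord(Seq(t.genomic_seq), id=t.transcript_id, name=t.gene_symbol or "SYNTH",
                       description=f"synthetic gene model for {t.transcript_id}")
    record.annotations["molecule_type"] = "DNA"
    strand = 1 if t.strand == "+" else -1

    def location(intervals):
        parts = [FeatureLocation(s - 1, e, strand=strand) for s, e in sorted(intervals)]
        return parts[0] if len(parts) == 1 else CompoundLocation(parts)

    gene_span = (min(s for s, _ in t.exons), max(e for _, e in t.exons))
    record.features.append(SeqFeature(
        FeatureLocation(gene_span[0] - 1, gene_span[1], strand=strand),
        type="gene", qualifiers={"gene": [t.gene_symbol]}))
    record.features.append(SeqFeature(
        location(t.exons), type="mRNA",
        qualifiers={"gene": [t.gene_symbol], "transcript_id": [t.transcript_id]}))
    cds_intervals = _cds_genomic_intervals(t)
    record.features.append(SeqFeature(
        location(cds_intervals), type="CDS",
        qualifiers={
            "gene": [t.gene_symbol],
            "transcript_id": [t.transcript_id],
            "translation": [t.protein_seq()],
        }))
    SeqIO.write(record, str(path), "genbank")


def _cds_genomic_intervals(t: TranscriptModel) -> list[tuple[int, int]]:
    """Genomic intervals of the CDS, exon by exon."""
    out = []
    mrna_cds = (t.utr5_len + 1, t.utr5_len + len(t.cds_seq))
    cum = 0
    for (gs, ge) in t.exons:
        l = ge - gs + 1
        lo = max(mrna_cds[0], cum + 1)
        hi = min(mrna_cds[1], cum + l)
        if lo <= hi:
            off_lo, off_hi = lo - cum, hi - cum  # 1-based offsets within exon
            if t.strand == "+":
                out.append((gs + off_lo - 1, gs + off_hi - 1))
            else:
                out.append((ge - off_hi + 1, ge - off_lo + 1))
        cum += l
    return out


# ---------------------------------------------------------------------------
# Structure pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructurePairSpec:
    length: int
    truncation_fraction: float = 1.0
    noise_sd: float = 0.0  # Å, isotropic on variant coordinates
    rigid_motion: bool = False
    plddt_profile: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 20:
            raise ValueError("invalid spec: length must be >= 20")
        if not 0.0 < self.truncation_fraction <= 1.0:
            raise ValueError("invalid spec: truncation fraction outside (0, 1]")


def make_structure_pair(
    spec: StructurePairSpec,
) -> tuple[StructureModel, StructureModel, float]:
    """Wild-type + variant Cα models with a known TM-score (or upper bound).

    The wild type is a jittered ideal helix (≈3.8 Å spacing, non-collinear);
    the variant keeps the first ``truncation_fraction`` of residues with
    optional rigid motion and Gaussian coordinate noise.  With zero noise
    the TM-score equals retained/total exactly; with noise it is an upper
    bound.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    i = np.arange(L)
    theta = np.deg2rad(100.0) * i
    coords = np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
    coords = coords + rng.normal(0.0, 0.15, size=(L, 3))
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=L))
    if spec.plddt_profile is not None:
        plddt = np.asarray(spec.plddt_profile, dtype=float)
        if plddt.shape != (L,):
            raise ValueError("invalid spec: pLDDT profile length mismatch")
    else:
        plddt = np.full(L, 70.0)

    wt = StructureModel(tuple(range(1, L + 1)), seq, coords, plddt,
                        model_id=f"wt_seed{spec.seed}", chain_id="A")

    n_var = max(1, round(spec.truncation_fraction * L))
    var_coords = coords[:n_var].copy()
    if spec.noise_sd > 0:
        var_coords = var_coords + rng.normal(0.0, spec.noise_sd, size=(n_var, 3))
    if spec.rigid_motion:
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-25.0, 25.0, size=3)
        var_coords = var_coords @ R.T + t
    var = StructureModel(tuple(range(1, n_var + 1)), seq[:n_var], var_coords,
                         plddt[:n_var].copy(),
                         model_id=f"var_seed{spec.seed}", chain_id="A")
    expected_tm = n_var / L
    return wt, var, expected_tm


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    n_patients: int
    n_families: int
    slope: float = 100.0
    intercept: float = 0.0
    family_intercept_sd: float = 6.0
    residual_sd: float = 8.0
    target_correlation: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_families <= self.n_patients:
            raise ValueError("invalid spec: n_families must be in [1, n_patients]")


def simulate_cohort(spec: CohortSpec):
    """Simulate a cohort: outcome = intercept + slope*x + family + noise.

    The predictor is uniform on (0, 1) (TM-score-like scale).  When
    ``target_correlation`` is given, the two noise SDs are rescaled jointly
    (preserving their ratio) so the marginal predictor-outcome correlation
    is the target; a target of 0 zeroes the slope instead.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_patients, spec.n_families
    fam = np.arange(n) % m
    x = rng.uniform(0.0, 1.0, size=n)
    slope = spec.slope
    fam_sd, res_sd = spec.family_intercept_sd, spec.residual_sd
    if spec.target_correlation is not None:
        rho = spec.target_correlation
        if rho == 0:
            slope = 0.0
        else:
            var_x = 1.0 / 12.0
            need = slope ** 2 * var_x * (1.0 / rho ** 2 - 1.0)
            have = fam_sd ** 2 + res_sd ** 2
            scale = np.sqrt(need / have) if have > 0 else 0.0
            fam_sd, res_sd = fam_sd * scale, res_sd * scale
    u = rng.normal(0.0, fam_sd, size=m)
    eps = rng.normal(0.0, res_sd, size=n)
    y = spec.intercept + slope * x + u[fam] + eps
    df = pd.DataFrame({
        "patient_id": [f"S{i + 1}" for i in range(n)],
        "family_id": [f"F{f + 1}" for f in fam],
        "tm_score": x,
        "FSIQ": y,
    })
    df.attrs["true_slope"] = slope
    df.attrs["family_sd"] = fam_sd
    df.attrs["residual_sd"] = res_sd
    return df
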