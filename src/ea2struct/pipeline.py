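"""End-to-end orchestration: variants → proteins → metrics → statistics.

`run_pipeline` wires the stages together and writes three report tables —
per-patient variant/structure metrics, the correlation table, and the
mixed-model table — each as a display TSV (fixed rounding) and a
machine-readable JSON with unrounded values.  The structure stage is
optional so the statistical reproduction runs from printed inputs alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort_stats import (
    COGNITIVE_INDICES,
    adjust_fdr,
    bh_fdr,
    fit_lmm_random_intercept,
    load_ea2_cohort,
    pearson,
    spearman,
    summarize,
    vif_two_predictors,
)
from .gene_models import TranscriptModel, load_transcript
from .nmd_classifier import classify_nmd
from .structure_metrics import lcr_percent, mean_plddt, read_model, tm_score
from .variant_engine import (
    WILDTYPE_LENGTH,
    aa_percent,
    apply_variants,
    model_intron_retention,
    parse_cdna_variant,
    predicted_length_from_p_notation,
    protein_consequence,
    translate_cds,
)

__all__ = ["PipelineConfig", "run_pipeline", "variant_metrics_table",
           "structure_metrics_table", "correlation_table", "lmm_table",
           "cohort_with_metrics", "PipelineError"]

log = logging.getLogger("ea2struct")

# display rounding, aligned with the precision of the published tables
ROUND_TM = 3
ROUND_R = 3
ROUND_AA = 1
ROUND_PLDDT = 2
ROUND_LCR = 2


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name."""


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str
    variants_tsv: str | None = None
    cohort_tsv: str | None = None  # None -> packaged 13-patient fixture
    transcript_path: str | None = None  # GenBank, or use transcript_gff3+fasta
    transcript_gff3: str | None = None
    transcript_fasta: str | None = None
    transcript_id: str | None = None
    wildtype_structure: str | None = None
    structures_dir: str | None = None
    skip_structures: bool = True
    wildtype_length: int = WILDTYPE_LENGTH

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for key in ("variants_tsv", "cohort_tsv", "transcript_path",
                    "transcript_gff3", "transcript_fasta",
                    "wildtype_structure", "structures_dir"):
            val = getattr(self, key)
            if val is not None and not os.path.exists(val):
                raise PipelineError(f"config: {key} path does not exist: {val}")
        if not self.skip_structures:
            if not self.wildtype_structure or not self.structures_dir:
                raise PipelineError(
                    "config: structure stage enabled but wild-type model or "
                    "model directory missing")


# ---------------------------------------------------------------------------
# Variant stage
# ---------------------------------------------------------------------------

def _consequences_for_patient(t: TranscriptModel, hgvs_list: list[str],
                              wildtype_length: int):
    """Per-variant p. notations plus the compound (cis) product metrics."""
    wt_protein = t.protein_seq()
    variants = [parse_cdna_variant(h) for h in hgvs_list]
    coding = [v for v in variants if v.kind != "intronic_substitution"]
    intronic = [v for v in variants if v.kind == "intronic_substitution"]
    if len(intronic) > 1:
        raise PipelineError("variants: multiple splice variants per allele unsupported")

    per_variant = []
    for v in coding:
        prot, term = translate_cds(apply_variants(t.cds_seq, [v]))
        per_variant.append(protein_consequence(wt_protein, prot, term))
    if intronic:
        coding_region = model_intron_retention(t, intronic[0])
        if coding:
            raise PipelineError(
                "variants: cis combination of splice and coding variants unsupported")
        prot, term = translate_cds(coding_region)
        compound = protein_consequence(wt_protein, prot, term, splice=True)
        per_variant.append(compound)
    elif len(coding) == 1:
        compound = per_variant[0]
    else:
        prot, term = translate_cds(apply_variants(t.cds_seq, coding))
        compound = protein_consequence(wt_protein, prot, term)

    nmd = classify_nmd(t, compound, variants) if (
        compound.has_ptc or compound.consequence_class in
        ("missense", "synonymous", "inframe_deletion", "inframe_insertion")
    ) else None
    return per_variant, compound, nmd


def variant_metrics_table(
    variants_df: pd.DataFrame,
    transcript: TranscriptModel | None = None,
    wildtype_length: int = WILDTYPE_LENGTH,
) -> pd.DataFrame:
    """Per-patient variant consequences (Table-2 shape, minus structures).

    With a transcript model the consequences are computed from the cDNA
    changes; without one, predicted lengths come from the ``hgvs_p`` (or
    ``predicted_length``) column — the printed-inputs-only path.
    """
    rows = []
    for _, rec in variants_df.iterrows():
        hgvs_list = [h.strip() for h in str(rec["hgvs_c"]).split(";") if h.strip()]
        row = {
            "patient_id": rec["patient_id"],
            "family_id": rec.get("family_id", ""),
            "hgvs_c": ";".join(hgvs_list),
        }
        if transcript is not None:
            per_variant, compound, nmd = _consequences_for_patient(
                transcript, hgvs_list, wildtype_length)
            row["exonic_function"] = ",".join(c.consequence_class for c in per_variant)
            row["hgvs_p"] = ", ".join(c.p_notation for c in per_variant)
            row["predicted_length"] = compound.predicted_length
            row["wildtype_length"] = compound.wildtype_length
            row["aa_percent"] = compound.aa_percent
            row["predicted_nmd"] = nmd.verdict if nmd is not None else "NA"
        else:
            if "predicted_length" in rec and pd.notna(rec.get("predicted_length")):
                length = int(rec["predicted_length"])
            else:
                p_parts = [p.strip() for p in str(rec["hgvs_p"]).split(",")]
                length = min(
                    predicted_length_from_p_notation(p, wildtype_length)
                    for p in p_parts)
            row["hgvs_p"] = rec.get("hgvs_p", "")
            row["predicted_length"] = length
            row["wildtype_length"] = wildtype_length
            row["aa_percent"] = aa_percent(length, wildtype_length)
            row["predicted_nmd"] = "NA"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Structure stage
# ---------------------------------------------------------------------------

def structure_metrics_table(
    wildtype_path, structures_dir, patient_ids,
) -> pd.DataFrame:
    """TM-score / mean pLDDT / LCR% per patient model against the wild type."""
    wt = read_model(wildtype_path)
    structures_dir = Path(structures_dir)
    rows = []
    for pid in patient_ids:
        hits = sorted(structures_dir.glob(f"{pid}.*"))
        hits = [h for h in hits if h.suffix.lower() in (".cif", ".mmcif", ".pdb", ".ent")]
        if not hits:
            raise PipelineError(f"structure: model not found for patient {pid}")
        var = read_model(hits[0])
        res = tm_score(wt, var)
        rows.append({
            "patient_id": pid,
            "tm_score": res.tm,
            "mean_plddt": mean_plddt(var),
            "lcr_percent": lcr_percent(var),
            "n_aligned": res.n_aligned,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Statistics stage
# ---------------------------------------------------------------------------

def cohort_with_metrics(cohort: pd.DataFrame,
                        wildtype_length: int = WILDTYPE_LENGTH) -> pd.DataFrame:
    """Ensure the derived AA columns exist on a cohort table."""
    df = cohort.copy()
    if "aa_raw" not in df:
        df["aa_raw"] = 100.0 * df["predicted_length"] / df.get(
            "wildtype_length", wildtype_length)
    if "aa_fraction" not in df:
        df["aa_fraction"] = df["aa_raw"] / 100.0
    if "aa_percent" not in df:
        df["aa_percent"] = [
            aa_percent(int(l), int(w)) for l, w in zip(
                df["predicted_length"],
                df.get("wildtype_length", pd.Series([wildtype_length] * len(df))))
        ]
    return df


def correlation_table(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlations of TM-score (Pearson) and AA% (Spearman) with each index.

    Returns ``(correlations, summaries)``.  Spearman runs on the unrounded
    AA fraction; all ten p-values form one BH-FDR family.
    """
    df = cohort_with_metrics(cohort)
    results, meta = [], []
    for idx in COGNITIVE_INDICES:
        results.append(pearson(df["tm_score"], df[idx]))
        meta.append(("TM-score", idx))
    for idx in COGNITIVE_INDICES:
        results.append(spearman(df["aa_raw"], df[idx]))
        meta.append(("AA%", idx))
    results = adjust_fdr(results)
    rows = []
    for (pred, idx), res in zip(meta, results):
        rows.append({
            "predictor": pred, "index": idx, "method": res.method,
            "r": res.r, "ci_lo": res.ci95[0] if res.ci95 else None,
            "ci_hi": res.ci95[1] if res.ci95 else None,
            "p": res.p, "p_fdr": res.p_fdr, "n": res.n,
        })
    summaries = pd.DataFrame(
        [{"index": s.index_name, "mean": s.mean, "sd": s.sd} for s in summarize(df)])
    return pd.DataFrame(rows), summaries


def lmm_table(cohort: pd.DataFrame, method: str = "ml") -> pd.DataFrame:
    """Family-random-intercept LMMs per index (Table-4 shape).

    For each cognitive index: univariable TM-score, univariable AA
    (fraction scale), and the two-predictor model.  The twenty p-values
    form one BH-FDR family.
    """
    df = cohort_with_metrics(cohort)
    rows = []
    for idx in COGNITIVE_INDICES:
        y, g = df[idx], df["family_id"]
        tm, aa = df["tm_score"], df["aa_fraction"]
        (r_tm,) = fit_lmm_random_intercept(y, tm, g, method=method,
                                           term_names=["TM-score"])
        (r_aa,) = fit_lmm_random_intercept(y, aa, g, method=method,
                                           term_names=["AA%"])
        r_tm2, r_aa2 = fit_lmm_random_intercept(
            y, pd.concat([tm, aa], axis=1), g, method=method,
            term_names=["TM-score (adjusted for AA%)",
                        "AA% (adjusted for TM-score)"])
        for res in (r_tm, r_aa, r_tm2, r_aa2):
            rows.append({
                "index": idx, "predictor": res.term, "beta": res.beta,
                "ci_lo": res.ci95[0], "ci_hi": res.ci95[1], "p": res.p,
                "df": res.df, "var_family": res.var_family,
                "var_resid": res.var_resid, "converged": res.converged,
            })
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _write_table(df: pd.DataFrame, out_dir: Path, name: str, rounding=None) -> None:
    disp = df.copy()
    if rounding:
        for col, nd in rounding.items():
            if col in disp:
                disp[col] = disp[col].map(
                    lambda v: "" if pd.isna(v) else f"{v:.{nd}f}")
    disp.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    with open(out_dir / f"{name}.json", "w") as fh:
        json.dump(json.loads(df.to_json(orient="records")), fh, indent=1)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run all configured stages; write report tables; return them."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, pd.DataFrame] = {}

    transcript = None
    if config.transcript_path or config.transcript_gff3:
        try:
            source = (config.transcript_path if config.transcript_path
                      else (config.transcript_gff3, config.transcript_fasta))
            transcript = load_transcript(source, config.transcript_id)
        except Exception as exc:
            raise PipelineError(f"gene-models: {exc}") from exc

    variant_metrics = None
    if config.variants_tsv:
        try:
            variants_df = pd.read_csv(config.variants_tsv, sep="\t")
        except Exception as exc:
            raise PipelineError(f"variants: {exc}") from exc
        if variants_df.empty:
            log.warning("variant list is empty; statistics stage will be skipped")
            report["variant_metrics"] = pd.DataFrame()
            _write_table(pd.DataFrame(), out_dir, "variant_metrics")
            _write_run_log(config, out_dir)
            return report
        try:
            variant_metrics = variant_metrics_table(
                variants_df, transcript, config.wildtype_length)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"variants: {exc}") from exc
        report["variant_metrics"] = variant_metrics

    if not config.skip_structures:
        pids = (list(variant_metrics["patient_id"]) if variant_metrics is not None
                else None)
        if pids is None:
            raise PipelineError("structure: no patient list (variants stage required)")
        try:
            struct_df = structure_metrics_table(
                config.wildtype_structure, config.structures_dir, pids)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"structure: {exc}") from exc
        report["structure_metrics"] = struct_df
        if variant_metrics is not None:
            variant_metrics = variant_metrics.merge(struct_df, on="patient_id")
            report["variant_metrics"] = variant_metrics

    if variant_metrics is not None:
        _write_table(variant_metrics, out_dir, "variant_metrics",
                     rounding={"aa_percent": ROUND_AA, "tm_score": ROUND_TM,
                               "mean_plddt": ROUND_PLDDT, "lcr_percent": ROUND_LCR})

    # cohort: explicit TSV, packaged fixture, or variant+structure join
    cohort = None
    if config.cohort_tsv:
        cohort = pd.read_csv(config.cohort_tsv, sep="\t")
    elif config.variants_tsv is None:
        cohort = load_ea2_cohort()
    if cohort is not None and variant_metrics is not None:
        join_cols = [c for c in ("predicted_length", "wildtype_length", "tm_score")
                     if c in variant_metrics and c not in cohort]
        if join_cols:
            cohort = cohort.merge(
                variant_metrics[["patient_id", *join_cols]], on="patient_id")

    if cohort is not None and {"tm_score"}.issubset(cohort.columns) and (
            "predicted_length" in cohort or "aa_raw" in cohort):
        try:
            cohort = cohort_with_metrics(cohort, config.wildtype_length)
            correlations, summaries = correlation_table(cohort)
            lmm = lmm_table(cohort)
            vif = vif_two_predictors(cohort["tm_score"], cohort["aa_raw"])
        except Exception as exc:
            raise PipelineError(f"stats: {exc}") from exc
        report["correlations"] = correlations
        report["summaries"] = summaries
        report["lmm"] = lmm
        _write_table(correlations, out_dir, "correlations",
                     rounding={"r": ROUND_R, "ci_lo": 2, "ci_hi": 2,
                               "p": 3, "p_fdr": 3})
        _write_table(summaries, out_dir, "summaries")
        _write_table(lmm, out_dir, "lmm",
                     rounding={"beta": 2, "ci_lo": 2, "ci_hi": 2,
                               "p": 3, "p_fdr": 3, "df": 1,
                               "var_family": 2, "var_resid": 2})
        with open(out_dir / "vif.json", "w") as fh:
            json.dump({"vif_tm_aa": vif}, fh)
            fh.write("\n")

    _write_run_log(config, out_dir)
    return report


def _write_run_log(config: PipelineConfig, out_dir: Path) -> None:
    with open(out_dir / "run_log.txt", "w") as fh:
        fh.write(f"ea2struct {__version__}\n")
        for f in dataclasses.fields(config):
            fh.write(f"{f.name}: {getattr(config, f.name)}\n")
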