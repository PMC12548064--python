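"""Descriptive tables, publication-style output and end-to-end
orchestration.

``describe_cohort`` reproduces the cohort descriptive table (counts and
percentages per conception group); ``render_results_table`` formats per-CpG
results with annotations in the candidate-table layout; ``run_pipeline``
chains simulate -> preprocess -> associate -> change -> power from a
single YAML-style config dict and writes all outputs plus a run
manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from methylong import __version__
from methylong.association import AssociationResult, run_association
from methylong.change import ChangeResult, run_change
from methylong.errors import AnalysisError
from methylong.io_data import (
    MethylationMatrix,
    ProbeAnnotation,
    SampleRecord,
    load_default_manifest,
    samples_at,
    write_manifest,
    write_matrix,
    write_sample_sheet,
)
from methylong.power import (
    PowerSpec,
    bonferroni_threshold,
    required_multiplier,
    simulate_power,
)
from methylong.preprocess import dedup_twins
from methylong.synthetic_cohort import (
    CohortSpec,
    EffectProfile,
    generate_cohort,
    generate_methylation,
)

logger = logging.getLogger(__name__)

_AGE_BANDS = [(-np.inf, 20), (20, 25), (25, 30), (30, 35), (35, np.inf)]
_AGE_LABELS = ["< 20", "[20, 25)", "[25, 30)", "[30, 35)", ">= 35"]


@dataclass
class CohortSummary:
    """Counts and percentages per covariate x conception group."""

    group_n: dict[str, int]
    tables: dict[str, dict[str, dict[str, tuple[int, float]]]]
    maternal_age_mean: dict[str, float]


def _pct(count: int, total: int) -> float:
    return round(100.0 * count / total, 1)


def describe_cohort(samples: Sequence[SampleRecord]) -> CohortSummary:
    """Descriptive statistics on a twin-deduplicated sheet, one row per
    child (timepoints collapsed)."""
    by_child: dict[str, list[SampleRecord]] = {}
    for rec in samples:
        by_child.setdefault(rec.child_id, []).append(rec)
    groups = ("natural", "ART")
    children = {g: [recs for recs in by_child.values()
                    if recs[0].conception == g] for g in groups}
    for g in groups:
        if not children[g]:
            raise AnalysisError(f"conception group {g!r} is empty")
    group_n = {g: len(children[g]) for g in groups}

    def tally(covariate, categories, classify) -> dict:
        out = {}
        for cat in categories:
            out[cat] = {}
            for g in groups:
                count = sum(1 for recs in children[g] if classify(recs) == cat)
                out[cat][g] = (count, _pct(count, group_n[g]))
        return out

    tables = {
        "timepoints": tally(
            "timepoints", ["2 time points", "1 time point"],
            lambda recs: f"{min(len(recs), 2)} time point"
            + ("s" if len(recs) >= 2 else "")),
        "sex": tally("sex", ["male", "female"], lambda recs: recs[0].sex),
        "birth_type": tally(
            "birth_type", ["Singleton", "Multiple (Twin)"],
            lambda recs: "Multiple (Twin)" if recs[0].multiple_birth
            else "Singleton"),
        "smoking": tally("smoking", ["No", "Sometimes", "Daily"],
                         lambda recs: recs[0].smoking),
        "bmi_category": tally(
            "bmi_category", ["Underweight", "Normal", "Overweight",
                             "Obese", "NA"],
            lambda recs: recs[0].bmi_category or "NA"),
        "parity": tally("parity", ["0", "1", "2", "3", "4+"],
                        lambda recs: str(min(recs[0].parity, 4))
                        + ("+" if recs[0].parity >= 4 else "")),
        "maternal_age_band": tally(
            "maternal_age_band", _AGE_LABELS,
            lambda recs: _AGE_LABELS[next(
                i for i, (lo, hi) in enumerate(_AGE_BANDS)
                if lo <= recs[0].maternal_age < hi)]),
    }
    maternal_age_mean = {
        g: round(float(np.mean([recs[0].maternal_age for recs in children[g]])), 1)
        for g in groups}
    return CohortSummary(group_n=group_n, tables=tables,
                         maternal_age_mean=maternal_age_mean)


def summary_to_tsv(summary: CohortSummary, path) -> None:
    rows = []
    for covariate, table in summary.tables.items():
        for cat, per_group in table.items():
            row = {"covariate": covariate, "category": cat}
            for g, (count, pct) in per_group.items():
                row[f"{g}_count"] = count
                row[f"{g}_pct"] = pct
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _fmt_coef(beta: float, lo: float, hi: float) -> str:
    if not np.isfinite(beta):
        return "NA"
    return f"{beta:.3f} ({lo:.3f}, {hi:.3f})"


def render_results_table(
    results: Sequence[Union[AssociationResult, ChangeResult]],
    manifest: Sequence[ProbeAnnotation],
) -> pd.DataFrame:
    """Candidate-table layout: probe, hg19 annotation, coefficient with
    95% CI, raw and FDR-adjusted p, sorted by genomic position."""
    if not results:
        raise AnalysisError("no results to render")
    ann = {p.probe_id: p for p in manifest}
    rows = []
    for r in results:
        a = ann.get(r.probe_id)
        if a is None:
            logger.warning("probe %s has no manifest annotation", r.probe_id)
        rows.append({
            "probe_id": r.probe_id,
            "chromosome": a.chromosome if a else "",
            "position": a.position if a else "",
            "regulatory_feature": a.regulatory_feature if a else "",
            "island_relation": a.island_relation if a else "",
            "gene": a.gene if a else "",
            "coefficient_95ci": _fmt_coef(r.beta_hat, r.ci_low, r.ci_high),
            "p_raw": "NA" if r.p_raw is None else f"{r.p_raw:.3f}",
            "p_fdr": "NA" if r.p_fdr is None else f"{r.p_fdr:.3f}",
            "n": getattr(r, "n_used", getattr(r, "n_children", "")),
        })
    df = pd.DataFrame(rows)
    order = np.argsort([ann[p].position if p in ann else np.inf
                        for p in df["probe_id"]], kind="stable")
    return df.iloc[order].reset_index(drop=True)


DEFAULT_CONFIG: dict = {
    "cohort": {},       # CohortSpec overrides
    "effects": {"delta_birth": 0.13, "delta_postnatal": 0.13},
    "mad_multiplier": 5.0,
    "power": {"n_iter": 2000, "base_n_natural": 247, "base_n_art": 81,
              "target_power": 0.80, "search": False},
}


def run_pipeline(config: Optional[dict], out_dir, seed: int = 1) -> Path:
    """Simulate a cohort and run every analysis stage, writing TSV/JSON
    outputs, a log of thresholds and seeds, and a run manifest."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = load_default_manifest()

    stage = "simulate"
    try:
        spec = CohortSpec(seed=seed, **cfg.get("cohort", {}))
        effects = EffectProfile.uniform(
            manifest,
            delta_birth=cfg["effects"].get("delta_birth", 0.0),
            delta_postnatal=cfg["effects"].get("delta_postnatal", 0.0))
        sheet = generate_cohort(spec)
        matrix = generate_methylation(sheet, manifest, effects, spec)
        write_sample_sheet(sheet, out / "sample_sheet.tsv")
        write_matrix(matrix, out / "methylation_m_values.tsv")
        write_manifest(manifest, out / "probe_manifest.tsv")

        stage = "preprocess"
        sheet = dedup_twins(sheet, seed=seed)

        stage = "describe"
        summary_to_tsv(describe_cohort(sheet), out / "cohort_descriptives.tsv")

        stage = "associate"
        k = cfg["mad_multiplier"]
        for tp in ("birth", "postnatal"):
            res = run_association(matrix, sheet, manifest, tp, mad_multiplier=k)
            render_results_table(res, manifest).to_csv(
                out / f"association_{tp}.tsv", sep="\t", index=False)

        stage = "change"
        sample_ids = {r.sample_id for r in sheet}
        birth_ids = [s for s in matrix.sample_ids
                     if s in sample_ids and s.endswith("_birth")]
        post_ids = [s for s in matrix.sample_ids
                    if s in sample_ids and not s.endswith("_birth")]
        change_res = run_change(matrix.subset(sample_ids=birth_ids),
                                matrix.subset(sample_ids=post_ids),
                                sheet, manifest, mad_multiplier=k)
        render_results_table(change_res, manifest).to_csv(
            out / "change.tsv", sep="\t", index=False)

        stage = "power"
        pcfg = cfg["power"]
        alpha = bonferroni_threshold(pcfg.get("alpha_family", 0.05),
                                     pcfg.get("n_tests", len(manifest)))
        pspec = PowerSpec(n_natural=pcfg["base_n_natural"],
                          n_art=pcfg["base_n_art"], alpha=alpha,
                          n_iter=pcfg["n_iter"], seed=seed)
        pres = simulate_power(pspec)
        power_out = {"alpha": alpha, "power": pres.power,
                     "mc_se": pres.mc_se, "spec": asdict(pres.spec)}
        if pcfg.get("search"):
            mult, at_target = required_multiplier(
                pcfg["base_n_natural"], pcfg["base_n_art"],
                pcfg["target_power"], spec=pspec)
            power_out["required_multiplier"] = mult
            power_out["power_at_multiplier"] = at_target.power
        (out / "power.json").write_text(json.dumps(power_out, indent=2))
    except Exception as exc:
        raise AnalysisError(f"pipeline stage {stage!r} failed: {exc}") from exc

    run_manifest = {
        "package_version": __version__,
        "seed": seed,
        "scale": "M",
        "config": {k: v for k, v in cfg.items()},
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2,
                                                      default=str))
    logger.info("pipeline complete: %s", out)
    return out


__all__ = [
    "CohortSummary", "DEFAULT_CONFIG", "describe_cohort", "render_results_table",
    "run_pipeline", "summary_to_tsv",
]
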