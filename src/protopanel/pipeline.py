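"""End-to-end orchestration: transform -> volcano -> screen -> lasso ->
AIC refinement -> per-marker ROC -> LOOCV, with every stage table written
to the output directory plus a JSON run manifest sufficient to reproduce
the run bit-exactly."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

from . import differential, evaluate, io, panel, screening
from .simulate import CohortDesign, simulate_cohort

logger = logging.getLogger("protopanel")


class PipelineError(RuntimeError):
    """A stage failed in a way the pipeline cannot continue from."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    expression_path: str | None = None
    labels_path: str | None = None
    design: CohortDesign | None = None
    d_n: int = 50
    fc_min: float = 0.2
    p_max: float = 0.05
    lambda_strategy: str = "cv"
    tol: float = panel.DEFAULT_COEF_TOL
    cutoff: float = 0.5
    t_variant: str = "welch"
    seed: int = 0
    out_dir: str = "protopanel_out"

    def __post_init__(self) -> None:
        has_files = self.expression_path is not None and self.labels_path is not None
        if has_files == (self.design is not None):
            raise ValueError("provide either expression+labels paths or a "
                             "simulation design, not both")
        if self.d_n < 1:
            raise ValueError("d_n must be a positive integer")
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must be in (0, 1)")
        for p in (self.expression_path, self.labels_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class PipelineResult:
    stats: list
    volcano_counts: differential.VolcanoCounts
    screening: screening.ScreeningResult
    lasso_model: panel.LogisticPanelModel
    lasso_support: list[str]
    refined: panel.StepAicResult
    rocs: list
    in_sample: evaluate.ClassificationMetrics
    loocv: evaluate.LoocvResult
    out_dir: Path


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full discovery pipeline and write all artifacts.

    Enforces the nesting screened set >= lasso support >= final panel and
    raises :class:`PipelineError` on an empty consensus (nothing to model).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.design is not None:
        matrix, labels = simulate_cohort(cfg.design)
        io.write_expression(matrix, out / "expression.csv")
        io.write_labels(labels, out / "labels.csv")
    else:
        matrix, labels = io.read_expression(cfg.expression_path, cfg.labels_path)
    logger.info("loaded %d subjects x %d markers (%d cases / %d controls)",
                matrix.n, matrix.p, labels.n_case, labels.n_control)

    std = io.log2_standardize(matrix)
    X = std.to_frame()

    stats = differential.compute_marker_stats(std, labels, t_variant=cfg.t_variant)
    thr = differential.VolcanoThresholds(fc_min=cfg.fc_min, p_max=cfg.p_max)
    counts, stats = differential.volcano_classify(stats, thr)
    differential.stats_to_frame(stats).to_csv(out / "volcano.csv", index=False)
    logger.info("volcano: %d up, %d down, %d ns of p=%d",
                counts.up, counts.down, counts.ns, matrix.p)

    scfg = screening.ScreeningConfig(d_n=min(cfg.d_n, std.p))
    screen = screening.consensus_screen(stats, scfg)
    screen.to_frame(stats).to_csv(out / "screening.csv", index=False)
    logger.info("screening: %d consensus markers at d_n=%d",
                len(screen.consensus), screen.d_n)
    if not screen.consensus:
        raise PipelineError("screening stage produced an empty consensus; "
                            "nothing to model")

    est = panel.LassoPanelLogistic(lambda_strategy=cfg.lambda_strategy,
                                   coef_tol=cfg.tol, random_state=cfg.seed)
    est.fit(X[screen.consensus], labels.status)
    lasso_model = est.to_panel_model()
    lasso_support = est.support_
    logger.info("lasso: %d of %d markers retained at lambda=%.5g",
                len(lasso_support), len(screen.consensus), est.lambda_)
    if not lasso_support:
        raise PipelineError("lasso stage retained no markers")

    refined = panel.step_aic_refine(X, labels, lasso_support)
    logger.info("stepAIC: final panel of %d markers (AIC %.3f)",
                len(refined.final_support), refined.trace[-1]["aic"])

    if not (set(screen.consensus) >= set(lasso_support)
            >= set(refined.final_support)):
        raise PipelineError("marker-set nesting violated "
                            "(screen >= lasso >= final)")

    panel.panel_table(lasso_model, refined.final_support, cfg.tol).to_csv(
        out / "panel.csv", index=False)

    rocs = [evaluate.roc_and_youden(X[m].to_numpy(), labels, m)
            for m in lasso_support]
    evaluate.roc_table(rocs).to_csv(out / "roc.csv", index=False)

    in_sample = panel.in_sample_metrics(lasso_model, X, labels, cfg.cutoff)
    loocv = evaluate.loocv_panel(X, labels, refined.final_support, cfg.cutoff)
    loocv.to_frame().to_csv(out / "loocv.csv", index=False)

    io.write_manifest(out / "metrics.json", {
        "in_sample": in_sample.as_dict(),
        "loocv": loocv.metrics.as_dict(),
        "loocv_ridged_folds": loocv.ridged_folds,
    })
    io.write_manifest(out / "manifest.json", {
        "config": dataclasses.asdict(cfg),
        "n": matrix.n, "p": matrix.p,
        "counts": {"p": matrix.p,
                   "volcano_up": counts.up, "volcano_down": counts.down,
                   "post_screen": len(screen.consensus),
                   "post_lasso": len(lasso_support),
                   "final_panel": len(refined.final_support)},
        "lambda": est.lambda_,
    })
    export_gene_list(refined.final_support, out / "gene_list.txt")
    logger.info("counts: p=%d screen=%d lasso=%d final=%d", matrix.p,
                len(screen.consensus), len(lasso_support),
                len(refined.final_support))

    return PipelineResult(
        stats=stats, volcano_counts=counts, screening=screen,
        lasso_model=lasso_model, lasso_support=lasso_support,
        refined=refined, rocs=rocs, in_sample=in_sample, loocv=loocv,
        out_dir=out,
    )


def export_gene_list(markers: list[str], path: str | Path | None = None) -> str:
    """One uppercase symbol per line, deduplicated, order preserved —
    ready to paste into external enrichment services (STRING, KEGG, GO)."""
    if not markers:
        raise ValueError("cannot export an empty marker list")
    seen: set[str] = set()
    lines = []
    for m in markers:
        u = str(m).upper()
        if u not in seen:
            seen.add(u)
            lines.append(u)
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
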