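"""End-to-end pipeline: decompose -> orient -> annotate -> survival ->
link -> project -> report.

Every stage persists its artifact as plain TSV/JSON under the output
directory, and the Markdown report is generated purely from those persisted
artifacts — regenerating the report without recomputation yields the
identical document.  All randomness flows from the single config seed, so
two runs with the same config produce byte-identical numerical outputs.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import json

import numpy as np
import pandas as pd
import yaml

from .ica import ConsensusICA, ConsensusICAResults
from .integration import cluster_components, link_components
from .matrix import ExpressionMatrix
from .projection import rank_profile
from .signatures import (component_signatures, orient_components,
                         orient_mirna_by_link, read_gmt, signatures_to_frame)
from .survival import ComponentCoxScreen, read_clinical_tsv

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "build_report"]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the failing stage."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Thresholds default to the conventional values: top-contributor
    adj.p < 0.01, survival adj.p < 0.05, link r² > 0.25.
    """

    expression: str                      # TSV, features x samples, log-like
    out: str
    k: int = 10
    nt: int = 20
    seed: int = 0
    threads: int = 1
    scale: str = "log2"
    alpha_contrib: float = 0.01
    alpha_survival: float = 0.05
    r2_threshold: float = 0.25
    clinical: str | None = None          # TSV: sample_id, time, event, labels
    gene_sets: str | None = None         # GMT
    mirna_expression: str | None = None  # second-layer TSV
    k_mirna: int | None = None
    new_samples: str | None = None       # TSV of samples to project
    component_prefix: str = "RIC"

    def __post_init__(self) -> None:
        for name in ("alpha_contrib", "alpha_survival", "r2_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.nt < 2:
            raise ValueError("nt must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _log(msg: str) -> None:
    print(f"[consensusica] {msg}", file=sys.stderr)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all configured stages; returns the output directory.

    Artifacts already written are retained if a later stage fails.
    """
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)

    _log(f"decompose: k={cfg.k} nt={cfg.nt} seed={cfg.seed}")
    res = _stage("decompose")(_decompose)(cfg)

    _log("orient + annotate")
    res, sigs = _stage("annotate")(_annotate)(cfg, res, out)
    res.save(out / "decomposition")

    if cfg.clinical:
        _log("survival screen + risk score")
        _stage("survival")(_survival)(cfg, res, out)

    if cfg.mirna_expression:
        _log("miRNA decomposition + linking")
        _stage("link")(_link)(cfg, res, out)

    if cfg.new_samples:
        _log("projection of new samples")
        _stage("project")(_project)(cfg, res, out)

    _log("report")
    _stage("report")(build_report)(out)
    return out


def _decompose(cfg: PipelineConfig) -> ConsensusICAResults:
    E = ExpressionMatrix.read_tsv(cfg.expression, scale=cfg.scale)
    model = ConsensusICA(E, n_components=cfg.k, n_runs=cfg.nt,
                         component_prefix=cfg.component_prefix)
    return model.fit(seed=cfg.seed, n_jobs=cfg.threads)


def _annotate(cfg: PipelineConfig, res: ConsensusICAResults, out: Path):
    gene_sets = None
    if cfg.gene_sets:
        gene_sets = read_gmt(cfg.gene_sets, background=res.feature_ids)
    res = orient_components(res, gene_sets, alpha=cfg.alpha_contrib)
    sigs = component_signatures(res, alpha=cfg.alpha_contrib)
    signatures_to_frame(sigs).to_csv(out / "signatures.tsv", sep="\t",
                                     index=False)
    return res, sigs


def _survival(cfg: PipelineConfig, res: ConsensusICAResults, out: Path) -> None:
    clin = read_clinical_tsv(cfg.clinical)
    screen = ComponentCoxScreen(res, clin).fit()
    screen.table.to_csv(out / "survival.tsv", sep="\t", index_label="component")
    model = screen.risk_score(alpha=cfg.alpha_survival)
    model.to_json(out / "risk_score_model.json")
    model.score(res.weights).to_frame().to_csv(out / "risk_scores.tsv",
                                               sep="\t", index_label="sample_id")


def _link(cfg: PipelineConfig, res: ConsensusICAResults, out: Path) -> None:
    E_mi = ExpressionMatrix.read_tsv(cfg.mirna_expression, scale=cfg.scale)
    k_mi = cfg.k_mirna or max(2, cfg.k // 2)
    res_mi = ConsensusICA(E_mi, n_components=k_mi, n_runs=cfg.nt,
                          component_prefix="MIC").fit(seed=cfg.seed,
                                                      n_jobs=cfg.threads)
    res_mi = orient_mirna_by_link(res_mi, res)
    res_mi.save(out / "decomposition_mirna")
    graph = link_components(res, res_mi, r2_threshold=cfg.r2_threshold)
    graph.to_tsv(out / "links.tsv")
    clusters = cluster_components(graph)
    rows = [(i + 1, ";".join(c["members"])) for i, c in enumerate(clusters)]
    pd.DataFrame(rows, columns=["cluster", "members"]).to_csv(
        out / "clusters.tsv", sep="\t", index=False)


def _project(cfg: PipelineConfig, res: ConsensusICAResults, out: Path) -> None:
    E_new = ExpressionMatrix.read_tsv(cfg.new_samples, scale=cfg.scale)
    W_new = res.project(E_new)
    W_new.to_csv(out / "weights_new.tsv", sep="\t", index_label="component_id")
    rank_profile(res, W_new).to_csv(out / "ranking.tsv", sep="\t",
                                    index_label="sample_id")


# ---------------------------------------------------------------------------
# report: a pure function of the persisted artifacts
# ---------------------------------------------------------------------------

def _read_tsv(path: Path, **kwargs) -> pd.DataFrame | None:
    return pd.read_csv(path, sep="\t", **kwargs) if path.exists() else None


def build_report(out_dir) -> Path:
    """Render report.md from the artifacts in ``out_dir``.

    Content is read exclusively from the persisted files, so the report is
    reproducible from the output directory alone.
    """
    out = Path(out_dir)
    dec = out / "decomposition"
    meta = json.loads((dec / "meta.json").read_text())
    stability = pd.read_csv(dec / "stability.tsv", sep="\t", index_col=0)
    sigs = _read_tsv(out / "signatures.tsv")
    surv = _read_tsv(out / "survival.tsv", index_col=0)
    rs = _read_tsv(out / "risk_scores.tsv", index_col=0)
    links = _read_tsv(out / "links.tsv")
    clusters = _read_tsv(out / "clusters.tsv")
    ranking = _read_tsv(out / "ranking.tsv", index_col=0)

    lines = ["# Consensus ICA report", "",
             f"Decomposition: k={meta['k']}, nt={meta['nt']}, "
             f"seed={meta['seed']}, converged runs "
             f"{meta['n_converged']}/{meta['nt']}.", "",
             "## Components", ""]
    for cid, row in stability.iterrows():
        lines.append(f"### {cid}")
        lines.append("")
        lines.append(f"- stability R2: {row.iloc[0]:.4f}")
        if sigs is not None:
            sub = sigs[sigs["component"] == cid]
            n_pos = int((sub["side"] == "positive").sum())
            n_neg = int((sub["side"] == "negative").sum())
            lines.append(f"- top contributors: {n_pos} positive, {n_neg} negative")
        if surv is not None and cid in surv.index:
            r = surv.loc[cid]
            flag = " (significant)" if r["adj_p"] < 0.05 else ""
            lines.append(f"- survival: LHR={r['LHR']:.4f}, "
                         f"adj_p={r['adj_p']:.3e}{flag}")
        if links is not None and len(links):
            hits = links[(links["node_a"].str.endswith(f":{cid}"))
                         | (links["node_b"].str.endswith(f":{cid}"))]
            if len(hits):
                partners = sorted(set(hits["node_a"]) | set(hits["node_b"]))
                lines.append(f"- linked components: {', '.join(partners)}")
        lines.append("")

    if clusters is not None:
        lines += ["## Component clusters", ""]
        for _, row in clusters.iterrows():
            lines.append(f"- cluster {row['cluster']}: {row['members']}")
        lines.append("")

    if rs is not None:
        lines += ["## Sample risk scores", "",
                  "| sample | RS |", "|---|---|"]
        for sid, row in rs.iterrows():
            lines.append(f"| {sid} | {row.iloc[0]:.4f} |")
        lines.append("")

    if ranking is not None:
        lines += ["## Ranking scores of projected samples", "",
                  "| sample | " + " | ".join(ranking.columns) + " |",
                  "|" + "---|" * (len(ranking.columns) + 1)]
        for sid, row in ranking.iterrows():
            lines.append("| " + " | ".join([str(sid)] +
                                           [f"{v:.3f}" for v in row]) + " |")
        lines.append("")

    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
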