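"""Reproducible orchestration: simulate/load -> normalize -> test -> report.

A run is driven by a single :class:`RunConfig` (optionally parsed from a
TOML file), executes the stages in a fixed order and writes every artifact
as TSV/Newick plus a JSON manifest with the config, the seeds and a SHA-256
checksum per artifact.  Re-running with the same config and seed reproduces
every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import ParameterError
from . import qpcr
from .cluster import SampleClustering, category_enrichment
from .contrasts import all_contrasts
from .io import (
    CohortDesign,
    ProbeMatrix,
    align,
    read_design,
    read_matrix,
    write_design,
    write_matrix,
)
from .normalize import grouping_check, median_center, pca
from .ordering import IntermediateOrdering
from .simulate import DeltaSpec, SimParams, simulate_cohort
from .subtype import subtype_anova, subtype_interaction

log = logging.getLogger("twindiff")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    matrix_path: str | None = None
    design_path: str | None = None
    simulate: SimParams | None = None
    fdr_q: float = 0.1
    contrasts: tuple[str, ...] = ("PvC", "UvC", "PvU")
    ordering_n_perm: int = 0
    cluster_distance: str = "correlation"
    cluster_linkage: str = "average"
    categories_path: str | None = None  # optional gene -> category TSV
    ct_path: str | None = None  # optional qPCR Ct table
    min_mag: float = 1.1
    seed: int = 0
    out_dir: str = "twindiff_run"

    def __post_init__(self) -> None:
        if not (0 < self.fdr_q < 1):
            raise ParameterError("fdr_q must lie in (0, 1)")
        have_files = self.matrix_path is not None and self.design_path is not None
        if not have_files and self.simulate is None:
            self.simulate = SimParams(seed=self.seed)
        for p in (self.matrix_path, self.design_path, self.categories_path, self.ct_path):
            if p is not None and not Path(p).exists():
                raise ParameterError(f"input path does not exist: {p}")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim = raw.pop("simulate", None)
        if sim is not None:
            delta = sim.pop("delta_log2", None)
            params = SimParams(**sim)
            if delta is not None:
                params.delta_log2 = DeltaSpec(**delta)
            raw["simulate"] = params
        if "contrasts" in raw:
            raw["contrasts"] = tuple(raw["contrasts"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def emit_frame(df: pd.DataFrame, name: str, **kw) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=kw.pop("index", False), float_format="%.6g")
        artifacts.append(p)

    stage = "load"
    try:
        if config.simulate is not None:
            stage = "simulate"
            log.info("stage simulate")
            matrix, design, truth = simulate_cohort(config.simulate)
            write_matrix(matrix, out / "matrix.tsv")
            write_design(design, out / "design.tsv")
            truth.write(out / "truth.tsv")
            artifacts += [out / "matrix.tsv", out / "design.tsv", out / "truth.tsv"]
        else:
            log.info("stage load")
            matrix = read_matrix(config.matrix_path)
            design = read_design(config.design_path)
            matrix = align(matrix, design)

        stage = "normalize"
        log.info("stage normalize")
        normalized = median_center(matrix, design)
        write_matrix(normalized, out / "normalized.tsv")
        artifacts.append(out / "normalized.tsv")

        stage = "pca_qc"
        k = min(3, len(design.samples) - 1, len(normalized.probe_ids))
        qc_rows = []
        labels = pd.DataFrame(
            {"role": design.roles(), "batch": design.batches()},
            index=design.subject_ids,
        )
        for tag, m in (("raw", matrix), ("normalized", normalized)):
            res = pca(m, k)
            emit_frame(res.to_frame(labels), f"pca_{tag}.tsv", index=True)
            for label_col in ("role", "batch"):
                pv = grouping_check(res, labels[label_col].to_numpy())
                qc_rows += [
                    {"stage": tag, "label": label_col, "component": i + 1, "p": p}
                    for i, p in enumerate(pv)
                ]
        emit_frame(pd.DataFrame(qc_rows), "pca_grouping.tsv")

        stage = "contrasts"
        log.info("stage contrasts")
        tables = all_contrasts(normalized, design, config.fdr_q)
        for name in config.contrasts:
            emit_frame(tables[name], f"contrast_{name}.tsv")
        pvc = tables["PvC"]
        selected = pvc.loc[
            pvc["fdr"].notna() & (pvc["fdr"] <= config.fdr_q), "probe_id"
        ].tolist()
        emit_frame(pd.DataFrame({"probe_id": selected}), "selected_PvC.tsv")

        stage = "ordering"
        log.info("stage ordering")
        summaries = []
        for label, subset in (("all", None), ("bh_selected_PvC", selected)):
            if subset is not None and not subset:
                continue
            est = IntermediateOrdering(
                probe_subset=subset,
                n_perm=config.ordering_n_perm,
                seed=config.seed,
                label=label,
            ).fit(normalized, design)
            r = est.result_
            emit_frame(r.per_probe, f"ordering_{label}.tsv", index=True)
            summaries.append(
                {
                    "subset": label,
                    "n": r.n,
                    "k": r.k,
                    "fraction": r.fraction,
                    "p_binomial": r.p_binomial,
                    "p_permutation": r.p_permutation,
                }
            )
        emit_frame(pd.DataFrame(summaries), "ordering_summary.tsv")

        stage = "subtype"
        log.info("stage subtype")
        emit_frame(subtype_anova(normalized, design, config.fdr_q), "subtype_anova.tsv")
        emit_frame(
            subtype_interaction(normalized, design, config.fdr_q),
            "subtype_interaction.tsv",
        )

        stage = "cluster"
        log.info("stage cluster")
        subset = selected if len(selected) >= 2 else None
        clust = SampleClustering(
            probe_subset=subset,
            distance=config.cluster_distance,
            linkage=config.cluster_linkage,
        ).fit(normalized, design)
        (out / "dendrogram.nwk").write_text(clust.dendrogram_.to_newick())
        artifacts.append(out / "dendrogram.nwk")
        emit_frame(
            pd.DataFrame(
                {
                    "sample_id": clust.leaf_order_,
                    "branch": clust.branches_[clust.leaf_order_].to_numpy(),
                    "role": [
                        dict(zip(design.subject_ids, design.roles()))[s]
                        for s in clust.leaf_order_
                    ],
                }
            ),
            "cluster_leaves.tsv",
        )

        if config.categories_path:
            stage = "enrichment"
            log.info("stage enrichment")
            cats = pd.read_csv(config.categories_path, sep="\t", dtype=str)
            universe = set(normalized.probe_ids)
            sel = set(selected)
            rows = []
            for cat, grp in cats.groupby(cats.columns[1]):
                members = set(grp.iloc[:, 0]) & universe
                k_in = len(members & sel)
                if sel:
                    rows.append(
                        {
                            "category": cat,
                            "k": k_in,
                            "n": len(sel),
                            "K": len(members),
                            "N": len(universe),
                            "p": category_enrichment(
                                k_in, len(sel), len(members), len(universe)
                            ),
                        }
                    )
            emit_frame(pd.DataFrame(rows), "enrichment.tsv")

        if config.ct_path:
            stage = "concordance"
            log.info("stage concordance")
            records = qpcr.read_ct_table(config.ct_path)
            by_gene: dict[str, dict[str, qpcr.CtRecord]] = {}
            for r in records:
                by_gene.setdefault(r.gene, {})[r.group] = r
            fold_by_probe = dict(zip(pvc["probe_id"], pvc["fold_signed"]))
            rows = []
            for gene, groups in sorted(by_gene.items()):
                if "case" not in groups or "calibrator" not in groups:
                    raise ParameterError(
                        f"gene {gene}: Ct table needs 'case' and 'calibrator' groups"
                    )
                rq_fold = qpcr.ratio_to_signed(qpcr.rq(groups["case"], groups["calibrator"]))
                array_fold = fold_by_probe.get(gene, np.nan)
                row = {"gene": gene, "rq_fold": rq_fold, "array_fold": array_fold}
                if not np.isnan(array_fold):
                    row["concordant"] = qpcr.trend_concordant(
                        rq_fold, array_fold, config.min_mag
                    )
                rows.append(row)
            emit_frame(pd.DataFrame(rows), "concordance.tsv")
    except Exception:
        log.error("stage %s failed", stage)
        raise

    manifest = {
        "config": config.to_jsonable(),
        "seed": config.seed,
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
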