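"""End-to-end pipeline: quant tables -> DS matrices -> PCA -> gene
selection -> characteristic isoforms, for every TPM threshold and both the
all-genes and the constrained (no-zero) variant, with a machine-readable
run manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import warnings
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import characteristic as chariso
from . import io as qio
from . import metrics, pca, selection
from .errors import PipelineError

log = logging.getLogger("splicedegree")

__all__ = ["PipelineConfig", "run_pipeline"]

_FLOAT_FMT = "%.10g"


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Inputs, thresholds and knobs of a full pipeline run."""

    quant_dir: str
    tx2gene: str
    metadata: str
    out_dir: str
    gene_subset: str | None = None
    annotation: str | None = None
    thresholds: tuple[float, ...] = (0.1, 1.0, 10.0)
    components: int = 2
    alpha: float = 0.01
    whisker_k: float = 1.5
    protein_coding_only: bool = True
    strip_versions: bool = True
    presence_rule: str = "any_sample"
    seed: int = 0

    def __post_init__(self) -> None:
        th = tuple(float(t) for t in self.thresholds)
        if not th or any(t <= 0 for t in th) or list(th) != sorted(th):
            raise ValueError("thresholds must be positive and sorted ascending")
        object.__setattr__(self, "thresholds", th)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        return cls(**raw)


def _write_selection(sel, out: Path, stem: str) -> None:
    sel.to_frame().to_csv(out / f"selection_{stem}.tsv", sep="\t",
                          float_format=_FLOAT_FMT)
    selection.export_gene_list(sel, out / f"genes_{stem}.txt")


def _analyse_variant(ds: metrics.DSMatrix, metadata: pd.DataFrame,
                     config: PipelineConfig, out: Path) -> dict:
    """DS -> PCA -> per-component selection for one threshold/variant."""
    out.mkdir(parents=True, exist_ok=True)
    ds.to_tsv(out / "ds.tsv")
    info: dict = {"n_genes": int(ds.ds.shape[0])}
    n_samples = ds.ds.shape[1]
    max_comp = min(n_samples - 1, ds.ds.shape[0])
    if max_comp < 1:
        log.warning("variant at %s has no genes; PCA and selection skipped", out)
        return info

    n_comp = min(config.components, max_comp)
    result = pca.run_pca(ds, n_components=n_comp)
    pca.scores_table(result, metadata).to_csv(
        out / "pca_scores.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    result.loadings.to_csv(out / "pca_loadings.tsv", sep="\t",
                           index_label="gene_id", float_format=_FLOAT_FMT)
    pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(n_comp)],
            "explained_variance": result.explained_variance,
            "explained_variance_ratio": result.explained_variance_ratio,
        }
    ).to_csv(out / "pca_explained_variance.tsv", sep="\t", index=False,
             float_format=_FLOAT_FMT)
    info["explained_variance_ratio"] = [
        float(r) for r in result.explained_variance_ratio
    ]

    if ds.ds.shape[0] >= 4:
        for comp in range(1, n_comp + 1):
            sel = selection.select_genes(
                result, ds, metadata, component=comp,
                whisker_k=config.whisker_k, alpha=config.alpha,
            )
            _write_selection(sel, out, f"pc{comp}")
            info[f"selected_pc{comp}"] = int(len(sel.significant_genes))
    else:
        log.warning("fewer than 4 genes at %s; outlier selection skipped", out)
    return info


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for each threshold x {all, nonzero} combination.

    Writes all tables under ``config.out_dir`` plus ``manifest.json``; the
    same config and inputs produce byte-identical outputs.  Any stage
    failure aborts with the stage name, removing partial outputs.
    """
    out_dir = Path(config.out_dir)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "read-inputs"
    try:
        metadata = qio.read_metadata(config.metadata)
        tx2gene = qio.read_tx2gene(config.tx2gene, strip_versions=config.strip_versions)
        columns = qio.load_quant_dir(config.quant_dir, metadata,
                                     strip_versions=config.strip_versions)
        stage = "assemble-matrix"
        matrix = qio.assemble_matrix(
            columns, tx2gene, metadata,
            protein_coding_only=config.protein_coding_only,
        )
        if config.gene_subset:
            subset = qio.read_gene_list(config.gene_subset,
                                        strip_versions=config.strip_versions)
            matrix = matrix.subset_genes(subset)
            log.info("restricted to %d transcripts of the gene subset",
                     matrix.tpm.shape[0])
        annotation = (
            chariso.read_annotation(config.annotation) if config.annotation else None
        )

        manifest: dict = {
            "tool": "splicedegree",
            "version": __version__,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
            },
            "n_samples": int(matrix.tpm.shape[1]),
            "n_transcripts": int(matrix.tpm.shape[0]),
            "n_genes": int(matrix.gene_of.nunique()),
            "thresholds": {},
        }

        for thr in config.thresholds:
            stage = f"threshold-{thr:g}"
            tdir = out_dir / f"thr{thr:g}"
            tdir.mkdir(parents=True, exist_ok=True)
            entry: dict = {}

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                overall = metrics.overall_splicing(matrix, metadata, thr)
            overall.rename_axis("type").to_csv(
                tdir / "overall_splicing.tsv", sep="\t", float_format=_FLOAT_FMT
            )
            entry["overall_splicing"] = {
                str(k): (None if pd.isna(v) else float(v)) for k, v in overall.items()
            }

            ds_all = metrics.degree_of_splicing(matrix, thr)
            entry["all_genes"] = _analyse_variant(ds_all, metadata, config,
                                                  tdir / "all_genes")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ds_nz = metrics.restrict_nonzero(ds_all)
            entry["nonzero_only"] = _analyse_variant(ds_nz, metadata, config,
                                                     tdir / "nonzero_only")

            presence = chariso.presence_by_type(matrix, metadata, thr,
                                                rule=config.presence_rule)
            table = chariso.build_table(chariso.find_characteristic(presence),
                                        annotation)
            table.to_csv(tdir / "characteristic_isoforms.tsv", sep="\t", index=False)
            entry["n_characteristic"] = int(len(table))
            entry["status_tally"] = chariso.tally_status(table)
            manifest["thresholds"][f"{thr:g}"] = entry

        stage = "write-manifest"
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return manifest
    except Exception as exc:
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
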