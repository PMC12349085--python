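"""End-to-end pipeline: spectra -> landmarks -> alignment -> ordination ->
clustering -> discriminant model -> attribution, with reproducible outputs.

``run_pipeline`` executes the whole chain from a manifest + spectrum files
and writes delimited tables, JSON-serialised models and a plain-text log into
a run directory; ``classify_unknown`` formats new spectra with a completed
run's conventions and returns clade posteriors.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import (
    DEFAULT_TOLERANCE_KEV,
    DiscriminanceProfile,
    discriminance_profile,
    report_discriminant_regions,
)
from .batch_align import average_pseudoreplicates, realign_sessions
from .classify import (
    LDAModel,
    analysis_classes,
    fit_lda,
    loocv,
    predict_posterior,
    singleton_class_mask,
)
from .clustering import FAMILIES, gmm_cluster_bic, kmeans_cluster, ward_cluster
from .ordination import PCAResult, fit_pca, project
from .spectra import LandmarkMatrix, landmark_vector, load_landmark_matrix, read_manifest, read_spectrum

logger = logging.getLogger(__name__)

_CONFIG_KEYS = {
    "manifest", "spectra_dir", "outdir", "reference_session", "n_pcs_clustering",
    "n_pcs_lda", "cluster_k", "cluster_k_max", "gmm_families", "seed",
    "label_mapping", "drop_singletons", "tolerance_kev", "top_fraction",
    "priors_mode",
}


@dataclass
class PipelineConfig:
    manifest: str = "manifest.csv"
    spectra_dir: str = "."
    outdir: str = "run"
    reference_session: str = "DiffAbs-2018"
    n_pcs_clustering: int = 6
    n_pcs_lda: int = 21
    cluster_k: int = 2
    cluster_k_max: int = 3
    gmm_families: tuple[str, ...] = FAMILIES
    seed: int = 0
    label_mapping: dict = field(default_factory=dict)
    drop_singletons: bool = True
    tolerance_kev: float = DEFAULT_TOLERANCE_KEV
    top_fraction: float = 0.1
    priors_mode: str = "proportional"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "gmm_families" in raw:
            raw["gmm_families"] = tuple(raw["gmm_families"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["gmm_families"] = list(d["gmm_families"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")

    def digest(self) -> str:
        d = asdict(self)
        d["gmm_families"] = list(d["gmm_families"])
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    matrix_raw: LandmarkMatrix
    matrix_merged: LandmarkMatrix
    pca0: PCAResult
    pca1: PCAResult
    clusters: dict
    clade_matrix: LandmarkMatrix
    clade_labels: np.ndarray
    pca_clade: PCAResult
    lda: LDAModel
    loocv_outside: object
    loocv_inside: object
    profile: DiscriminanceProfile
    regions: pd.DataFrame
    run_dir: Path | None = None


def _pca_to_json(pca: PCAResult) -> dict:
    return {
        "center": pca.center.tolist(),
        "loadings": pca.loadings.tolist(),
        "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
    }


def _pca_from_json(d: dict) -> PCAResult:
    loadings = np.asarray(d["loadings"])
    return PCAResult(
        scores=np.zeros((0, loadings.shape[1])),
        loadings=loadings,
        explained_variance_ratio=np.asarray(d["explained_variance_ratio"]),
        center=np.asarray(d["center"]),
        labels=tuple(f"PC{i + 1}" for i in range(loadings.shape[1])),
    )


def _lda_to_json(lda: LDAModel) -> dict:
    return {
        "classes": lda.classes.tolist(),
        "means": lda.means.tolist(),
        "pooled_cov": lda.pooled_cov.tolist(),
        "scalings": lda.scalings.tolist(),
        "axis_separation": lda.axis_separation.tolist(),
        "priors": lda.priors.tolist(),
        "n_pcs": lda.n_pcs,
        "label_mapping": lda.label_mapping,
    }


def _lda_from_json(d: dict) -> LDAModel:
    return LDAModel(
        classes=np.asarray(d["classes"], dtype=object),
        means=np.asarray(d["means"]),
        pooled_cov=np.asarray(d["pooled_cov"]),
        scalings=np.asarray(d["scalings"]),
        axis_separation=np.asarray(d["axis_separation"]),
        priors=np.asarray(d["priors"]),
        n_pcs=int(d["n_pcs"]),
        label_mapping=dict(d["label_mapping"]),
    )


def run_pipeline(
    config: PipelineConfig,
    matrix: LandmarkMatrix | None = None,
    write: bool = True,
) -> PipelineResult:
    """Execute the full analysis chain.

    Reads the manifest and spectrum files from the config paths unless a
    pre-built ``matrix`` is supplied (the simulator's in-memory route).  With
    ``write=True`` all artifacts go to ``config.outdir``.
    """
    stage = "setup"
    log_lines: list[str] = [f"xrfmorph {__version__} | config {config.digest()}"]

    def note(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    try:
        if matrix is None:
            stage = "read"
            manifest = read_manifest(config.manifest)
            matrix = load_landmark_matrix(manifest, config.spectra_dir)
        note(f"landmarked {matrix.n_rows} spectra ({matrix.grid.size} landmarks each)")

        stage = "ordinate (pre-alignment)"
        pca0 = fit_pca(matrix)

        stage = "align"
        if matrix.meta["session"].nunique() > 1:
            aligned, deltas = realign_sessions(matrix, config.reference_session)
            for d in deltas:
                note(f"realigned {d.session} -> {d.reference_session} ({d.n_pairs} homologous pairs)")
        else:
            aligned = matrix
            aligned.aligned = True
            note("single session; realignment vacuous")
        merged = average_pseudoreplicates(aligned)
        note(f"averaged pseudo-replicates: {matrix.n_rows} -> {merged.n_rows} rows")

        stage = "ordinate"
        pca1 = fit_pca(merged)
        note(f"PCA on merged matrix: PC1 {pca1.explained_variance_ratio[0]:.1%}, "
             f"top-4 cumulative {pca1.cumulative_ratio(4):.1%}")

        stage = "cluster"
        scores6 = pca1.scores[:, : config.n_pcs_clustering]
        km = kmeans_cluster(scores6, config.cluster_k, seed=config.seed)
        ward2 = ward_cluster(scores6, config.cluster_k)
        ward3 = ward_cluster(scores6, config.cluster_k + 1)
        gmm_result, gmm_spec = gmm_cluster_bic(
            scores6, k_range=[config.cluster_k], families=config.gmm_families, seed=config.seed
        )
        note(f"GMM-BIC at k={config.cluster_k}: selected family {gmm_spec.family} (BIC {gmm_spec.bic:.1f})")
        clusters = {"kmeans": km, "ward_k2": ward2, "ward_k3": ward3, "gmm": gmm_result, "gmm_spec": gmm_spec}

        stage = "classify"
        labels_all = analysis_classes(merged.meta, config.label_mapping)
        if config.drop_singletons:
            drop = singleton_class_mask(merged.meta, labels_all)
            if drop.any():
                dropped = sorted(set(labels_all[drop]))
                note(f"dropped {int(drop.sum())} spectra of singleton class(es) {dropped}")
            clade_matrix = merged.select(~drop)
            clade_labels = labels_all[~drop]
        else:
            clade_matrix = merged
            clade_labels = labels_all
        pca_clade = fit_pca(clade_matrix)
        lda = fit_lda(
            pca_clade.scores[:, : config.n_pcs_lda],
            clade_labels,
            priors_mode=config.priors_mode,
            n_pcs=config.n_pcs_lda,
            label_mapping=config.label_mapping,
        )
        rep_out = loocv(clade_matrix, clade_labels, n_pcs=config.n_pcs_lda, mode="pca_outside",
                        priors_mode=config.priors_mode)
        rep_in = loocv(clade_matrix, clade_labels, n_pcs=config.n_pcs_lda, mode="pca_inside",
                       priors_mode=config.priors_mode)
        note(f"LOOCV accuracy: {rep_out.accuracy:.1%} (PCA outside folds), "
             f"{rep_in.accuracy:.1%} (PCA inside folds)")

        stage = "attribute"
        profile = discriminance_profile(pca_clade, lda)
        regions = report_discriminant_regions(
            profile, top_fraction=config.top_fraction, tolerance=config.tolerance_kev
        )
        note(f"{len(regions)} discriminant energy interval(s) above the "
             f"{1 - config.top_fraction:.0%} score quantile")
    except Exception as err:
        zone_ctx = ""
        raise RuntimeError(f"pipeline stage {stage!r} failed{zone_ctx}: {err}") from err

    result = PipelineResult(
        config=config, matrix_raw=matrix, matrix_merged=merged, pca0=pca0, pca1=pca1,
        clusters=clusters, clade_matrix=clade_matrix, clade_labels=clade_labels,
        pca_clade=pca_clade, lda=lda, loocv_outside=rep_out, loocv_inside=rep_in,
        profile=profile, regions=regions,
    )
    if write:
        result.run_dir = _write_run(result, log_lines)
    return result


def _write_run(result: PipelineResult, log_lines: list[str]) -> Path:
    cfg = result.config
    run_dir = Path(cfg.outdir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "config.yaml")

    def scores_df(pca: PCAResult, meta: pd.DataFrame, k: int = 21) -> pd.DataFrame:
        k = min(k, pca.scores.shape[1])
        df = pd.DataFrame(pca.scores[:, :k], columns=[f"PC{i + 1}" for i in range(k)])
        df.insert(0, "zone_id", meta["zone_id"].to_numpy())
        df.insert(1, "session", meta["session"].to_numpy())
        return df

    scores_df(result.pca0, result.matrix_raw.meta).to_csv(run_dir / "pca0_scores.csv", index=False)
    scores_df(result.pca1, result.matrix_merged.meta).to_csv(run_dir / "pca1_scores.csv", index=False)
    pd.DataFrame({
        "component": [f"PC{i + 1}" for i in range(result.pca1.n_components)],
        "explained_variance_ratio": result.pca1.explained_variance_ratio,
    }).to_csv(run_dir / "pca1_variance.csv", index=False)
    result.clusters["gmm"].diagnostics["bic_table"].to_csv(run_dir / "gmm_bic_table.csv", index=False)
    cluster_df = pd.DataFrame({
        "zone_id": result.matrix_merged.meta["zone_id"],
        "kmeans": result.clusters["kmeans"].labels,
        "ward_k2": result.clusters["ward_k2"].labels,
        "ward_k3": result.clusters["ward_k3"].labels,
        "gmm": result.clusters["gmm"].labels,
    })
    cluster_df.to_csv(run_dir / "cluster_labels.csv", index=False)
    result.loocv_outside.confusion.to_csv(run_dir / "loocv_confusion.csv")
    with open(run_dir / "loocv.json", "w") as fh:
        json.dump({
            "accuracy_pca_outside": result.loocv_outside.accuracy,
            "accuracy_pca_inside": result.loocv_inside.accuracy,
            "n_rows": int(len(result.clade_labels)),
            "classes": sorted(map(str, set(result.clade_labels))),
        }, fh, indent=2)
    regions = result.regions.copy()
    regions["elements"] = regions["elements"].map("; ".join)
    regions.to_csv(run_dir / "discriminant_intervals.csv", index=False)
    pd.DataFrame({"energy_kev": result.profile.grid, "score": result.profile.score}).to_csv(
        run_dir / "discriminance_profile.csv", index=False
    )
    with open(run_dir / "model.json", "w") as fh:
        json.dump({
            "version": __version__,
            "config_digest": cfg.digest(),
            "pca": _pca_to_json(result.pca_clade),
            "lda": _lda_to_json(result.lda),
        }, fh)
    (run_dir / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return run_dir


def classify_unknown(run_dir: str | Path, spectrum_paths: Sequence[str | Path]) -> pd.DataFrame:
    """Classify new spectra with a completed run's saved PCA + LDA.

    Each file is formatted with the run's conventions, projected into the
    saved ordination and scored; returns one row per spectrum with the class
    posteriors and the hard label.  Assumes acquisition comparable to the
    run's reference session (new-session offsets cannot be re-estimated
    without control spectra).
    """
    run_dir = Path(run_dir)
    with open(run_dir / "model.json") as fh:
        model_d = json.load(fh)
    pca = _pca_from_json(model_d["pca"])
    lda = _lda_from_json(model_d["lda"])
    rows = []
    for path in spectrum_paths:
        spec = read_spectrum(path)
        lm = landmark_vector(spec)
        scores = project(pca, lm)[:, : lda.n_pcs]
        post, hard = predict_posterior(lda, scores)
        row = {"spectrum": str(path), "predicted": hard[0]}
        row.update({f"p_{c}": p for c, p in zip(lda.classes, post[0])})
        rows.append(row)
    return pd.DataFrame(rows)
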