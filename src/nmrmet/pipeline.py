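"""End-to-end orchestration: simulate/load -> bucket -> PQN -> models ->
validation -> discriminant selection -> pathway mapping -> report files.

Every run writes its resolved configuration, a manifest with content hashes,
and per-model summaries; a fixed seed reproduces every numeric output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import load_library, metabolite_bucket_indices
from .multivariate import (
    ModelSpec,
    ResponseMatrix,
    correlation_loadings,
    cv_anova,
    fit_opls,
    fit_pca,
    fit_pls,
    permutation_test,
    q2y_loo,
    score_distances,
    select_discriminant,
)
from .pathway import load_network, map_metabolites, write_dot, extract_subnetwork
from .plots import loading_plot, score_plot
from .preprocess import (
    BucketTable,
    build_table,
    pqn_normalize,
    read_spectrum,
    reference_to_acetate,
    scale,
)
from .synthetic import default_design, generate_cohort, write_cohort

log = logging.getLogger("nmrmet")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "select_n_orthogonal"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Defaults follow the reference protocol: 0.001 ppm buckets, 4.6-5.0 ppm
    water exclusion, PQN + centering/unit-variance, 999 permutations,
    |R| >= 0.5 discriminant threshold."""

    out_dir: str = "run"
    spectra_dir: str | None = None  # None -> simulate the default cohort
    metadata: str | None = None
    bucket_width: float = 0.001
    excluded_regions: list[tuple[float, float]] = field(default_factory=lambda: [(4.6, 5.0)])
    reference_acetate: bool = False
    pqn: bool = True
    scaling: str = "center_unit_variance"
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [("unmanipulated", "sham"), ("sham", "sepsis_survivor")]
    )
    n_orthogonal: dict[str, int] | None = None  # "neg:pos" -> count; None -> auto rule
    n_permutations: int = 999
    r_threshold: float = 0.5
    seed: int = 0
    library: str | None = None  # None -> packaged fixture
    network: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.excluded_regions = [tuple(r) for r in cfg.excluded_regions]
        cfg.contrasts = [tuple(c) for c in cfg.contrasts]
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["excluded_regions"] = [list(r) for r in self.excluded_regions]
        data["contrasts"] = [list(c) for c in self.contrasts]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def select_n_orthogonal(
    X_unscaled,
    y,
    scaling: str = "center_unit_variance",
    improvement: float = 0.02,
    cap: int = 5,
) -> tuple[int, float]:
    """Add orthogonal components while LOO Q2Y improves by more than
    ``improvement``; returns (n_orthogonal, Q2Y)."""
    n = np.asarray(X_unscaled).shape[0] if not hasattr(X_unscaled, "values") else X_unscaled.values.shape[0]
    best_k = 0
    best_q2 = q2y_loo(X_unscaled, y, ModelSpec("opls", 1, 0), scaling).q2y
    for k in range(1, min(cap, n - 3) + 1):
        q2 = q2y_loo(X_unscaled, y, ModelSpec("opls", 1, k), scaling).q2y
        if q2 > best_q2 + improvement:
            best_k, best_q2 = k, q2
        else:
            break
    return best_k, best_q2


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o).__name__)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; on failure, keep partial outputs and drop a FAILED
    marker naming the stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    stage = "configure"
    try:
        config.to_yaml(out / "config.yaml")
        manifest: dict = {
            "version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "seed": config.seed,
            "models": {},
            "files": {},
        }

        stage = "spectra"
        if config.spectra_dir is None:
            log.info("no spectra directory given: simulating the default cohort")
            design = default_design(seed=config.seed)
            spectra, meta = generate_cohort(design)
            write_cohort(spectra, meta, out / "spectra")
        else:
            src = Path(config.spectra_dir)
            meta = pd.read_csv(config.metadata or src / "metadata.csv")
            spectra = [
                read_spectrum(src / f"{sid}.txt", sample_id=str(sid))
                for sid in meta["sample_id"]
            ]
        labels = [str(g) for g in meta["group"]]

        stage = "preprocess"
        if config.reference_acetate:
            spectra = [reference_to_acetate(s) for s in spectra]
        table = build_table(spectra, width=config.bucket_width, exclude=config.excluded_regions)
        if config.pqn:
            table = pqn_normalize(table)
        table.to_csv(out / "table.csv")
        scaled = scale(table, method=config.scaling)

        stage = "annotate"
        library = load_library(config.library)
        assignments = metabolite_bucket_indices(library, table.bucket_centers)
        detected = [name for name, idx in assignments.items() if idx]

        stage = "pca"
        n_comp = min(5, table.n_samples - 1, table.n_buckets)
        pca = fit_pca(scaled, n_comp)
        dist = score_distances(pca)
        pd.DataFrame(
            {"sample_id": table.sample_ids, "score_distance": dist}
        ).to_csv(out / "pca_distances.csv", index=False)
        manifest["models"]["pca"] = {
            "n_components": n_comp,
            "explained_variance_ratio": pca.explained_variance_ratio,
        }

        stage = "pls_3group"
        response = ResponseMatrix.from_labels(table.sample_ids, labels)
        if len(response.classes) > 1:
            n_pls = min(len(response.classes), table.n_samples - 1)
            pls = fit_pls(scaled, response, n_pls)
            cv = q2y_loo(table, response, ModelSpec("pls", n_pls, 0), config.scaling)
            pls_dir = out / "models" / "pls_all_groups"
            pls_dir.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(
                pls.T_pred,
                index=table.sample_ids,
                columns=[f"t{i + 1}" for i in range(pls.T_pred.shape[1])],
            ).to_csv(pls_dir / "scores.csv")
            summary = {
                "kind": "pls",
                "classes": response.classes,
                "n_components": n_pls,
                "R2Y": pls.R2Y,
                "Q2Y": cv.q2y,
                "cv_anova_p": cv_anova(cv),
            }
            (pls_dir / "summary.json").write_text(json.dumps(summary, indent=1, default=_json_default))
            score_plot(pls, labels, pls_dir / "score_plot.svg", title="PLS, all groups")
            manifest["models"]["pls_all_groups"] = summary

        for neg, pos in config.contrasts:
            stage = f"opls_{neg}_vs_{pos}"
            mask = np.array([l in (neg, pos) for l in labels])
            if mask.sum() < 6:
                raise ValueError(f"contrast {neg}:{pos} has too few samples")
            sub_ids = [sid for sid, m in zip(table.sample_ids, mask) if m]
            sub_labels = [l for l, m in zip(labels, mask) if m]
            sub = BucketTable(
                sample_ids=sub_ids,
                bucket_centers=table.bucket_centers,
                values=table.values[mask],
                normalization=table.normalization,
                excluded_regions=table.excluded_regions,
            )
            y = ResponseMatrix.from_labels(sub_ids, sub_labels).binary(neg, pos)
            key = f"{neg}:{pos}"
            if config.n_orthogonal and key in config.n_orthogonal:
                n_orth = config.n_orthogonal[key]
                q2 = q2y_loo(sub, y, ModelSpec("opls", 1, n_orth), config.scaling).q2y
            else:
                n_orth, q2 = select_n_orthogonal(sub, y, config.scaling)
            spec = ModelSpec("opls", 1, n_orth)
            model = fit_opls(scale(sub, config.scaling), y, n_orth)
            report = permutation_test(
                sub, y, spec, n_permutations=config.n_permutations,
                seed=config.seed, scaling=config.scaling,
            )
            profile = correlation_loadings(sub, y)
            disc = select_discriminant(
                profile, assignments, threshold=config.r_threshold,
                intensities=np.median(sub.values, axis=0),
            )
            mdir = out / "models" / f"opls_{neg}_vs_{pos}"
            mdir.mkdir(parents=True, exist_ok=True)
            scores = pd.DataFrame({"sample_id": sub_ids, "group": sub_labels, "t_pred": model.T_pred[:, 0]})
            for k in range(model.n_orthogonal):
                scores[f"t_orth{k + 1}"] = model.T_orth[:, k]
            scores.to_csv(mdir / "scores.csv", index=False)
            pd.DataFrame(
                {
                    "bucket_ppm": profile.bucket_centers,
                    "covariance": profile.covariance,
                    "R": profile.R,
                }
            ).to_csv(mdir / "loadings.csv", index=False)
            pd.DataFrame(disc, columns=["metabolite", "R"]).to_csv(mdir / "discriminant.csv", index=False)
            score_plot(model, sub_labels, mdir / "score_plot.svg", title=f"OPLS {neg} vs {pos}")
            loading_plot(profile, mdir / "loading_plot.svg", title=f"OPLS {neg} vs {pos}")
            summary = {
                "kind": "opls",
                "contrast": [neg, pos],
                "n_predictive": 1,
                "n_orthogonal": n_orth,
                "R2Y": model.R2Y,
                "Q2Y": report.observed_Q2Y,
                "permutation_percentile_99": report.percentile_99,
                "permutation_p": report.p_value,
                "passes_permutation_rule": report.passes,
                "cv_anova_p": report.cv_anova_p,
                "discriminant": [{"metabolite": m, "R": r} for m, r in disc],
            }
            (mdir / "summary.json").write_text(json.dumps(summary, indent=1, default=_json_default))
            manifest["models"][f"opls_{neg}_vs_{pos}"] = summary

        stage = "pathways"
        network = load_network(config.network)
        last = config.contrasts[-1]
        disc_names = [
            d["metabolite"]
            for d in manifest["models"][f"opls_{last[0]}_vs_{last[1]}"]["discriminant"]
        ]
        pw = map_metabolites(network, detected, disc_names)
        pdir = out / "pathways"
        pdir.mkdir(exist_ok=True)
        pw.table.to_csv(pdir / "report.csv", index=False)
        if disc_names:
            sub_net = extract_subnetwork(network, disc_names)
            write_dot(sub_net, pw.node_states, pdir / "subnetwork.dot")
        manifest["pathways"] = {
            "top": pw.ranking[0] if pw.ranking else None,
            "unmatched": pw.unmatched,
        }

        stage = "manifest"
        for f in sorted(out.rglob("*")):
            if f.is_file() and f.name not in ("manifest.json", "run.log"):
                manifest["files"][str(f.relative_to(out))] = _sha256(f)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=_json_default))
    except BaseException as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        log.removeHandler(handler)
        handler.close()
        raise PipelineError(stage, exc) from exc
    log.removeHandler(handler)
    handler.close()
    return out
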