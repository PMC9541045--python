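"""End-to-end orchestration: simulate -> preprocess -> fit -> stats -> similarity.

:func:`run_full` executes the whole analysis deterministically from a
:class:`RunConfig`, staging all outputs in a temporary directory and
renaming it into place only on success, so a failed run leaves nothing
behind.  Every artifact is plain CSV/JSON and the manifest records the
seed, the config echo and a content checksum per file, making reruns
bit-identical and verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .chemometrics import fit_pipeline
from .preprocess import PreprocessConfig, preprocess_cohort
from .similarity import cohort_similarity
from .stats import correlate_covariate, nested_ttest
from .synth import REFERENCE_GROUP, GeneratorConfig, default_config, generate_cohort

__all__ = ["RunConfig", "run_full", "config_to_dict", "config_from_dict"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Complete configuration of a reproducible pipeline run."""

    generator: GeneratorConfig = field(default_factory=default_config)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    groups: tuple[str, ...] = (REFERENCE_GROUP, "exercised", "human")
    candidates: int = 10
    q: float = 0.01
    similarity_width: float = 100.0
    seed: int = 1
    outdir: str = "ramanmuscle-run"


def config_to_dict(config: RunConfig) -> dict:
    """Serialize a RunConfig to plain built-in types (YAML/JSON friendly)."""
    d = dataclasses.asdict(config)
    d["groups"] = list(config.groups)
    return d


def config_from_dict(d: dict) -> RunConfig:
    """Rebuild a RunConfig from :func:`config_to_dict` output (or YAML)."""
    from .synth import GroupEffect, PeakSpec

    d = dict(d)
    gen = dict(d.get("generator", {}))
    if gen:
        gen["peak_library"] = [PeakSpec(**p) for p in gen.get("peak_library", [])]
        gen["effects"] = [GroupEffect(**e) for e in gen.get("effects", [])]
        if "silica_bump" in gen and isinstance(gen["silica_bump"], dict):
            gen["silica_bump"] = PeakSpec(**gen["silica_bump"])
        if "grid" in gen:
            gen["grid"] = tuple(gen["grid"])
        if "covariate_model" in gen:
            gen["covariate_model"] = tuple(gen["covariate_model"])
        if "baseline" in gen:
            gen["baseline"] = tuple(gen["baseline"])
        d["generator"] = GeneratorConfig(**gen)
    else:
        d["generator"] = default_config()
    pp = dict(d.get("preprocess", {}))
    if "window" in pp:
        pp["window"] = tuple(pp["window"])
    d["preprocess"] = PreprocessConfig(**pp)
    d["groups"] = tuple(d.get("groups", (REFERENCE_GROUP, "exercised", "human")))
    return RunConfig(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(config: RunConfig) -> dict:
    """Run the full pipeline and write all artifacts to ``config.outdir``.

    Returns the run report (also written as ``manifest.json``).  Raises
    with the failing stage named; on failure no output directory appears.
    """
    outdir = Path(config.outdir)
    staging = outdir.with_name(outdir.name + ".staging")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    try:
        report = _run_into(config, staging)
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    if outdir.exists():
        shutil.rmtree(outdir)
    staging.rename(outdir)
    return report


def _run_into(config: RunConfig, staging: Path) -> dict:
    gen = dataclasses.replace(config.generator, seed=config.seed)

    logger.info("simulate: %d-group cohort, seed %d", len(config.groups), config.seed)
    cohort, truth = generate_cohort(gen, config.groups)
    rio.write_cohort(cohort, staging / "cohort.csv", layout="long")
    truth_payload = {
        s.subject_id: {
            "group": s.group,
            "covariate": s.covariate,
            "effect_scale": s.effect_scale,
        }
        for s in truth.subjects.values()
    }
    (staging / "truth.json").write_text(json.dumps(truth_payload, indent=1))

    logger.info("preprocess: %d spectra", len(cohort))
    matrix = preprocess_cohort(cohort, config.preprocess)
    processed = rio.Cohort(
        [
            rio.RamanSpectrum(matrix.grid, row, m)
            for row, m in zip(matrix.intensities, matrix.meta)
        ],
        name="processed",
    )
    rio.write_cohort(processed, staging / "processed.csv", layout="wide")

    logger.info("fit: PCA-fed LDA on the two mouse groups")
    mouse = matrix.subset([REFERENCE_GROUP, "exercised"])
    pca, model = fit_pipeline(mouse, n_candidates=config.candidates, q=config.q)
    pd.DataFrame(
        {"wavenumber": mouse.grid, "loading": model.ldf_loading}
    ).to_csv(staging / "ldf_loading.csv", index=False)
    scores_df = pd.DataFrame(
        {
            "acquisition_id": [m.acquisition_id for m in mouse.meta],
            "subject_id": [m.subject_id for m in mouse.meta],
            "group": [m.group for m in mouse.meta],
            "covariate": [
                "" if m.covariate is None else repr(m.covariate) for m in mouse.meta
            ],
            "ldf_score": model.scores,
        }
    )
    scores_df.to_csv(staging / "ldf_scores.csv", index=False)
    model_payload = {
        "selected_pcs": model.provenance["selected_pcs"],
        "fallback_used": model.provenance["fallback_used"],
        "weights": model.weights.tolist(),
        "pc_p_values": model.selection.p_values.tolist(),
        "group_order": list(model.group_order),
        "explained_variance_ratio_first10": pca.explained_variance_ratio[
            : config.candidates
        ].tolist(),
    }
    (staging / "model.json").write_text(json.dumps(model_payload, indent=1))

    logger.info("stats: nested t-test and covariate correlation")
    nt = nested_ttest(
        model.scores,
        [m.subject_id for m in mouse.meta],
        [m.group for m in mouse.meta],
    )
    exercised_mask = np.array([m.group == "exercised" for m in mouse.meta])
    cov_by_subject = {
        m.subject_id: m.covariate for m in mouse.meta if m.group == "exercised"
    }
    n_with_cov = sum(v is not None for v in cov_by_subject.values())
    corr = None
    if n_with_cov >= 3:
        corr = correlate_covariate(
            model.scores[exercised_mask],
            np.array([m.subject_id for m in mouse.meta])[exercised_mask],
            cov_by_subject,
        )
    else:
        logger.warning(
            "fewer than 3 exercised subjects with a covariate; "
            "skipping the distance correlation"
        )
    stats_payload = {
        "nested_ttest": {
            "f": nt.f_statistic,
            "df": [nt.df_between, nt.df_within],
            "p_value": nt.p_value,
            "icc": nt.icc,
            "group_means": nt.group_means,
        },
        "covariate_correlation": None
        if corr is None
        else {
            "r": corr.r,
            "r2": corr.r2,
            "p_value": corr.p_value,
            "slope": corr.slope,
            "intercept": corr.intercept,
            "n_subjects": corr.n_subjects,
        },
    }
    (staging / "stats.json").write_text(json.dumps(stats_payload, indent=1))
    lines = [
        "Nested t-test of LDF scores (spectra nested within subjects)",
        f"  groups: {nt.group_means}",
        f"  F(1, {nt.df_within}) = {nt.f_statistic:.4g}, p = {nt.p_value:.4g}",
        f"  intraclass correlation (spectra within subject): {nt.icc:.3f}",
    ]
    if corr is not None:
        lines += [
            "Per-subject mean LDF score vs distance run (exercised group)",
            f"  r = {corr.r:.4f} (r^2 = {corr.r2:.4f}), p = {corr.p_value:.4g}",
            f"  slope = {corr.slope:.4g} per km over n = {corr.n_subjects} subjects",
        ]
    (staging / "stats_report.txt").write_text("\n".join(lines) + "\n")

    sim_rows = []
    if "human" in config.groups:
        logger.info("similarity: windowed cosine vs the human cohort")
        for mouse_group in (REFERENCE_GROUP, "exercised"):
            prof = cohort_similarity(
                matrix, mouse_group, "human", width=config.similarity_width
            )
            for (lo, hi), v in zip(prof.window_edges, prof.values):
                sim_rows.append(
                    {
                        "comparison": f"{mouse_group}_vs_human",
                        "window_low": lo,
                        "window_high": hi,
                        "cosine": v,
                    }
                )
        pd.DataFrame(sim_rows).to_csv(staging / "similarity.csv", index=False)

    files = sorted(p.name for p in staging.iterdir())
    manifest = {
        "seed": config.seed,
        "config": config_to_dict(config),
        "files": {name: _sha256(staging / name) for name in files},
        "summary": {
            "n_spectra": len(cohort),
            "selected_pcs": model.provenance["selected_pcs"],
            "nested_p": nt.p_value,
            "covariate_r": None if corr is None else corr.r,
        },
    }
    # checksum covers the scientific config only, not the output location
    hashable = {k: v for k, v in manifest["config"].items() if k != "outdir"}
    manifest["config_checksum"] = hashlib.sha256(
        json.dumps(hashable, sort_keys=True).encode()
    ).hexdigest()
    (staging / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
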