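"""End-to-end pipeline: assemble -> PLS -> resampling -> networks -> CV.

`run_pipeline` executes every stage on in-memory inputs or files, writes all
artifacts as delimited text / JSON into the output directory, and records a
manifest (config echo, seeds, input checksums, per-stage shapes, warnings).
All randomness flows from one top-level seed, deterministically partitioned
across stages, so a fixed seed reproduces every numeric output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectome import GroupedDataset, ParcelAtlas, assemble, subset_atlas
from .crossval import cv_permutation_p, stratified_folds
from .networks import network_permutation_test, mean_squared_salience
from .pls import fit_pls, partial_corr_brainscores
from .resampling import bootstrap, permutation_test
from . import io as cio

log = logging.getLogger("connpls")

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]

#: stage names used to partition the top-level seed
_STAGES = ("permutation", "bootstrap", "netcontrib", "cv_folds", "cv_perm")


@dataclass
class RunConfig:
    """Settings of a full run; defaults mirror the reference analysis."""

    behaviors: tuple[str, ...] = ("ucla_ls", "rmie", "teq", "iri_pt", "iri_ec")
    covariates: tuple[str, ...] = (
        "site", "gender_female", "education", "neuroticism", "cognition",
    )
    networks_keep: tuple[str, ...] | None = None  # None = all in atlas
    n_perm: int = 10000
    n_boot: int = 10000
    bsr_threshold: float = 1.96
    netcontrib_n_perm: int = 1000
    cv_k: int = 5
    cv_n_perm: int = 1000
    n_lv_report: int = 2
    seed: int = 0
    output_dir: str | Path = "connpls_out"

    def __post_init__(self) -> None:
        for name in ("n_perm", "n_boot", "netcontrib_n_perm", "cv_k", "cv_n_perm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        return np.random.SeedSequence([int(self.seed), _STAGES.index(stage)])


@dataclass
class PipelineResult:
    lvs: list
    permutation: object
    bootstrap: object
    network: object
    cv_p: np.ndarray
    cv: object
    brainscore_partials: pd.DataFrame
    manifest: dict


def run_pipeline(
    config: RunConfig,
    dataset: GroupedDataset,
    atlas: ParcelAtlas,
    behavior_table: pd.DataFrame | None = None,
    write: bool = True,
) -> PipelineResult:
    """Run every stage on an assembled dataset and write artifacts."""
    out = Path(config.output_dir)
    warnings: list[str] = []

    if config.networks_keep is not None:
        atlas, _ = subset_atlas(atlas, config.networks_keep)

    expected_edges = atlas.n_parcels * (atlas.n_parcels - 1) // 2
    if dataset.n_edges != expected_edges:
        raise RuntimeError(
            f"stage connectome: dataset has {dataset.n_edges} edges but the "
            f"atlas implies {expected_edges}"
        )

    X, Y, groups = dataset.X, dataset.Y, dataset.groups

    log.info("PLS decomposition: X %s, Y %s", X.shape, Y.shape)
    lvs = _stage("pls", fit_pls, X, Y, groups, dataset.group_order)
    ties = [
        l for l in range(len(lvs) - 1) if np.isclose(lvs[l].s, lvs[l + 1].s)
    ]
    if ties:
        warnings.append(f"near-degenerate singular values at ranks {ties}")
        log.warning("near-degenerate singular values at ranks %s", ties)

    log.info("permutation test: %d permutations", config.n_perm)
    perm = _stage(
        "permutation", permutation_test, X, Y, groups,
        n_perm=config.n_perm,
        seed=np.random.default_rng(config.stage_seed("permutation")),
        group_order=dataset.group_order,
    )
    for lv, p in zip(lvs, perm.p_perm):
        lv.p_perm = float(p)

    n_lv = min(config.n_lv_report, len(lvs))
    log.info("bootstrap: %d resamples", config.n_boot)
    boot = _stage(
        "bootstrap", bootstrap, X, Y, groups,
        n_boot=config.n_boot,
        seed=np.random.default_rng(config.stage_seed("bootstrap")),
        group_order=dataset.group_order,
        threshold=config.bsr_threshold,
        n_lv=n_lv,
    )
    if boot.n_skipped:
        warnings.append(f"{boot.n_skipped} degenerate bootstrap resamples skipped")

    log.info("network contribution: %d label permutations", config.netcontrib_n_perm)
    net = _stage(
        "netcontrib", network_permutation_test,
        boot.bootstrap_ratio[0], atlas,
        n_perm=config.netcontrib_n_perm,
        seed=np.random.default_rng(config.stage_seed("netcontrib")),
        threshold=config.bsr_threshold,
    )
    net_salience = mean_squared_salience(lvs[0].v, atlas)

    log.info("cross-validation: k=%d, %d permutations", config.cv_k, config.cv_n_perm)
    folds = _stage(
        "cv_folds", stratified_folds, groups, config.cv_k,
        seed=np.random.default_rng(config.stage_seed("cv_folds")),
        group_order=dataset.group_order,
    )
    cv_p, cv = _stage(
        "cv", cv_permutation_p, X, Y, groups, folds,
        n_perm=config.cv_n_perm,
        seed=np.random.default_rng(config.stage_seed("cv_perm")),
        lv_indices=tuple(range(n_lv)),
        group_order=dataset.group_order,
    )

    partials = _brainscore_partials(
        config, lvs[:n_lv], dataset, behavior_table, warnings
    )

    manifest = {
        "software": {"name": "connpls", "version": __version__},
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in asdict(config).items()
        },
        "seed": int(config.seed),
        "shapes": {
            "X": list(X.shape),
            "Y": list(Y.shape),
            "n_parcels": atlas.n_parcels,
            "n_lv": len(lvs),
            "groups": {
                g: int(np.sum(groups == g)) for g in dataset.group_order
                if np.any(groups == g)
            },
        },
        "warnings": warnings,
    }

    result = PipelineResult(
        lvs=lvs, permutation=perm, bootstrap=boot, network=net, cv_p=cv_p,
        cv=cv, brainscore_partials=partials, manifest=manifest,
    )
    if write:
        _write_outputs(out, config, result, net_salience, atlas)
    return result


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"stage {name}: {exc}") from exc


def _brainscore_partials(config, lvs, dataset, behavior_table, warnings):
    """Partial correlations of brain scores with each behavior, per group."""
    rows = []
    if behavior_table is None:
        warnings.append("no behavior table with covariates; partials skipped")
        return pd.DataFrame(rows)
    tbl = behavior_table.set_index("participant_id").loc[
        list(dataset.participant_ids)
    ]
    cov_cols = [c for c in config.covariates if c in tbl.columns]
    missing_cov = set(config.covariates) - set(cov_cols)
    if missing_cov:
        warnings.append(f"covariates not in behavior table: {sorted(missing_cov)}")
    C = tbl[cov_cols].to_numpy(dtype=float) if cov_cols else None
    for lv in lvs:
        for g in dataset.group_order:
            idx = np.flatnonzero(dataset.groups == g)
            if idx.size == 0:
                continue
            for b, name in enumerate(dataset.behavior_names):
                y = dataset.Y[idx, b]
                scores = lv.brain_scores[idx]
                Cg = C[idx] if C is not None else None
                if Cg is not None:
                    ok = np.all(np.isfinite(Cg), axis=1) & np.isfinite(y)
                    y, scores, Cg = y[ok], scores[ok], Cg[ok]
                r, p = partial_corr_brainscores(scores, y, Cg)
                rows.append(
                    {"lv": lv.index, "group": g, "behavior": name, "r": r, "p": p}
                )
    return pd.DataFrame(rows)


def _write_outputs(out: Path, config: RunConfig, res: PipelineResult,
                   net_salience, atlas: ParcelAtlas) -> None:
    out.mkdir(parents=True, exist_ok=True)
    lv_scalars = [
        {
            "lv": lv.index,
            "singular_value": lv.s,
            "cov_explained": lv.cov_explained,
            "p_perm": lv.p_perm,
        }
        for lv in res.lvs
    ]
    cio.write_json({"latent_variables": lv_scalars}, out / "lv_summary.json")
    pd.DataFrame(
        {f"lv{lv.index}": lv.u for lv in res.lvs}
    ).to_csv(out / "behavior_saliences.tsv", sep="\t", index=False)
    pd.DataFrame(
        {f"lv{lv.index}": lv.v for lv in res.lvs}
    ).to_csv(out / "edge_saliences.tsv", sep="\t", index=False)
    pd.DataFrame(
        {f"lv{lv.index}": lv.brain_scores for lv in res.lvs}
    ).to_csv(out / "brain_scores.tsv", sep="\t", index=False)

    bsr = pd.DataFrame(res.bootstrap.bootstrap_ratio.T)
    bsr.columns = [f"lv{c}" for c in range(bsr.shape[1])]
    with open(out / "bootstrap_ratios.tsv", "w") as fh:
        fh.write(f"# threshold=+/-{config.bsr_threshold}\n")
        bsr.to_csv(fh, sep="\t", index=False)

    names = list(res.network.networks)
    for label, M in (
        ("netcontrib_pos_mean", res.network.pos),
        ("netcontrib_neg_mean", res.network.neg),
        ("netcontrib_pos_z", res.network.z_pos),
        ("netcontrib_neg_z", res.network.z_neg),
        ("netcontrib_pos_p", res.network.p_pos),
        ("netcontrib_neg_p", res.network.p_neg),
        ("net_salience_pos", net_salience.pos),
        ("net_salience_neg", net_salience.neg),
    ):
        pd.DataFrame(M, index=names, columns=names).to_csv(
            out / f"{label}.tsv", sep="\t"
        )

    cio.write_json(
        {
            "k": res.cv.k,
            "mean_test_corr": res.cv.mean_corr,
            "pooled_test_corr": res.cv.pooled_corr,
            "fold_corr": res.cv.fold_corr,
            "p_perm": res.cv_p,
        },
        out / "cv_summary.json",
    )
    if not res.brainscore_partials.empty:
        res.brainscore_partials.to_csv(
            out / "brainscore_partials.tsv", sep="\t", index=False
        )
    cio.write_json(res.manifest, out / "manifest.json")
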