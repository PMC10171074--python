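"""Desk-scale analysis: stratified errors, weight-fraction correlations,
intensivity audits, learning curves, and pseudoorbital export.

Error analysis is stratified by the localization index L (localized
L >= 0.8, delocalized L < 0.4), since localized orbitals are the regime
that separates intensive pooling heads.  For weight-bearing heads the
learned per-atom weights are compared with the reference localization
fractions via per-molecule Pearson correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ContractError,
    LabeledDataset,
    OrbpoolError,
    Record,
)
from .localization import stratify_by_L
from .model import LossConfig, ModelConfig, TrainedModel, train
from .tightbinding import GeneratorConfig, TBParams, compose_noninteracting, generate_dataset

__all__ = [
    "EvalReport",
    "stratified_rmse",
    "weight_correlations",
    "intensivity_audit",
    "learning_curve",
    "export_pseudoorbitals",
]

logger = logging.getLogger(__name__)


class UnsupportedHeadError(OrbpoolError):
    """The pooling head does not produce per-atom weights."""


@dataclass
class EvalReport:
    """Stratified RMSEs (eV) and per-molecule weight correlations."""

    rmse_overall: float
    rmse_localized: float | None
    rmse_delocalized: float | None
    rmse_middle: float | None
    n_records: dict[str, int]
    model_id: str = ""
    dataset_id: str = ""
    pearson_per_molecule: np.ndarray | None = field(default=None, repr=False)


def _predictions(model: TrainedModel, dataset: LabeledDataset) -> np.ndarray:
    needs_l = model.config.pooling.name == "coeff"
    out = np.empty(len(dataset))
    for i, (system, ref) in enumerate(dataset):
        fractions = ref.localization_fractions if needs_l else None
        out[i], _ = model.predict(system, fractions=fractions)
    return out


def _rmse(pred: np.ndarray, y: np.ndarray, idx: list[int]) -> float | None:
    if not idx:
        return None
    d = pred[idx] - y[idx]
    return float(np.sqrt(np.mean(d * d)))


def stratified_rmse(model: TrainedModel, dataset: LabeledDataset) -> EvalReport:
    """RMSE overall and per L-stratum; empty strata reported as absent."""
    pred = _predictions(model, dataset)
    y = np.array([ref.target_energy for _, ref in dataset])
    strata = stratify_by_L(dataset)
    all_idx = list(range(len(dataset)))
    return EvalReport(
        rmse_overall=_rmse(pred, y, all_idx),
        rmse_localized=_rmse(pred, y, strata.localized),
        rmse_delocalized=_rmse(pred, y, strata.delocalized),
        rmse_middle=_rmse(pred, y, strata.middle),
        n_records={
            "overall": len(dataset),
            "localized": len(strata.localized),
            "delocalized": len(strata.delocalized),
            "middle": len(strata.middle),
        },
        model_id=model.model_id,
        dataset_id=dataset.provenance,
    )


def _population_pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    """Population-covariance Pearson R; None when either side is degenerate."""
    a = a - a.mean()
    b = b - b.mean()
    va = float(a @ a)
    vb = float(b @ b)
    if va <= 1e-24 or vb <= 1e-24:
        return None
    return float((a @ b) / np.sqrt(va * vb))


def weight_correlations(
    model: TrainedModel, dataset: LabeledDataset, min_atoms: int = 3
) -> np.ndarray:
    """Per-molecule Pearson R between learned weights and reference l_i.

    Supported heads: softmax (weights reconstructed from eps), wa, owa.
    Molecules with fewer than ``min_atoms`` atoms or with zero variance in
    either vector are excluded; exclusions are logged.
    """
    head = model.config.pooling
    if head.name not in ("softmax", "wa", "owa"):
        raise UnsupportedHeadError(f"head {head.name!r} has no per-atom weights")
    rs: list[float] = []
    n_small = n_degenerate = n_missing = 0
    for system, ref in dataset:
        if ref.localization_fractions is None:
            n_missing += 1
            continue
        if system.n_atoms < min_atoms:
            n_small += 1
            continue
        _, w = model.predict(system)
        r = _population_pearson(w, ref.localization_fractions)
        if r is None:
            n_degenerate += 1
            continue
        rs.append(r)
    if n_small or n_degenerate or n_missing:
        logger.info(
            "weight_correlations excluded %d small, %d zero-variance, "
            "%d unlabeled molecules",
            n_small, n_degenerate, n_missing,
        )
    return np.array(rs)


def intensivity_audit(
    model: TrainedModel,
    dataset: LabeledDataset,
    ks: tuple[int, ...] = (2, 3, 5),
    separation: float | None = None,
) -> pd.DataFrame:
    """Replication audit: predictions on k non-interacting copies.

    For intensive heads the table reports |prediction(k copies) -
    prediction(monomer)| (should vanish); for the sum head it reports the
    ratio prediction(k copies) / (k * monomer) (should equal one).
    Copies are separated by more than twice the descriptor cutoff.
    """
    cutoff = model.config.descriptor.cutoff_radius
    if separation is None:
        separation = 2.0 * cutoff + 1.0
    if separation <= 2.0 * cutoff:
        raise ContractError(
            f"separation {separation} must exceed twice the cutoff ({2 * cutoff})"
        )
    head = model.config.pooling
    needs_l = head.name == "coeff"
    rows = []
    for i, (system, ref) in enumerate(dataset):
        p1, _ = model.predict(
            system, fractions=ref.localization_fractions if needs_l else None
        )
        for k in ks:
            sup_sys, sup_ref = compose_noninteracting(
                [(system, ref)] * k, separation, descriptor_cutoff=cutoff
            )
            pk, _ = model.predict(
                sup_sys,
                fractions=sup_ref.localization_fractions if needs_l else None,
            )
            row = {"record": i, "k": k, "monomer": p1, "replicated": pk}
            if head.is_intensive:
                row["abs_deviation"] = abs(pk - p1)
            else:
                row["ratio"] = pk / (k * p1)
            rows.append(row)
    return pd.DataFrame(rows)


def learning_curve(
    generator_cfg: GeneratorConfig,
    model_cfgs: dict[str, ModelConfig],
    sizes: list[int],
    seeds: list[int],
    params: TBParams | None = None,
    loss_cfgs: dict[str, LossConfig] | None = None,
    n_test: int = 200,
    **train_kwargs,
) -> pd.DataFrame:
    """Stratified-RMSE learning curves over random training subsamples.

    A pool of ``generator_cfg.n_molecules`` molecules plus a fixed
    held-out test set of ``n_test`` molecules are generated once; for each
    (head, size, seed) a fresh subsample of the pool is drawn and a model
    trained on it, then evaluated per stratum on the fixed test set.
    Long-format rows: head, size, seed, stratum, rmse, n_records.
    """
    if sorted(sizes) != list(sizes):
        raise ContractError("sizes must be ascending")
    params = params or TBParams()
    pool = generate_dataset(generator_cfg, params)
    test_cfg = GeneratorConfig(
        **{**generator_cfg.__dict__, "seed": generator_cfg.seed + 10_000,
           "n_molecules": n_test, "substituent_library": generator_cfg.substituent_library}
    )
    test_ds = generate_dataset(test_cfg, params)
    if max(sizes) > len(pool):
        raise ContractError(f"size {max(sizes)} exceeds pool of {len(pool)}")
    loss_cfgs = loss_cfgs or {}
    rows = []
    for head_name, model_cfg in model_cfgs.items():
        for size in sizes:
            for seed in seeds:
                rng = np.random.default_rng(seed)
                idx = rng.choice(len(pool), size=size, replace=False)
                sub = pool.subset(idx)
                cfg = ModelConfig(**{**model_cfg.__dict__, "seed": seed})
                m = train(sub, cfg, loss_cfgs.get(head_name), **train_kwargs)
                report = stratified_rmse(m, test_ds)
                for stratum in ("overall", "localized", "delocalized", "middle"):
                    rmse = getattr(report, f"rmse_{stratum}")
                    if rmse is None:
                        continue
                    rows.append({
                        "head": head_name, "size": size, "seed": seed,
                        "stratum": stratum, "rmse": rmse,
                        "n_records": report.n_records[stratum],
                    })
    df = pd.DataFrame(rows)
    stats = (
        df.groupby(["head", "size", "stratum"])["rmse"]
        .agg(["mean", "std"]).reset_index()
        .rename(columns={"mean": "rmse_mean", "std": "rmse_std"})
    )
    return df.merge(stats, on=["head", "size", "stratum"])


def export_pseudoorbitals(
    model: TrainedModel, dataset: LabeledDataset, path
) -> None:
    """Write extended XYZ with reference l_frac and learned owa_weight columns.

    The learned weights can be rendered as semitransparent spheres
    (phase-less pseudoorbitals) next to the reference distribution in any
    structure viewer that reads extended XYZ.
    """
    from .core import write_extxyz

    head = model.config.pooling
    if head.name not in ("softmax", "wa", "owa"):
        raise UnsupportedHeadError(f"head {head.name!r} has no per-atom weights")
    weights = []
    for system, _ in dataset:
        _, w = model.predict(system)
        weights.append(w)
    out = LabeledDataset(
        records=list(dataset.records),
        split_tags=list(dataset.split_tags),
        provenance=dataset.provenance,
    )
    out.pseudoorbital_weights = weights
    write_extxyz(out, path)
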