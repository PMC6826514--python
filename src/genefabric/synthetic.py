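"""Seeded, ground-truth-labeled synthetic spot-level expression data.

The generator emulates the design of a replicated two-color microarray
study: a handful of conditions profiled in 4 biological replicates each,
every transcript probed redundantly by 1..28 spots, multiplicative
(log-normal) replicate noise with programmable coefficients of variation,
and latent replicate-level factors that impose positive or negative
correlation between designated gene pairs.  Foreground/background channel
intensities, plus injected control / corrupted / low-signal spots, exercise
the validity filter.

Noise model (log-additive): on the log2 scale the replicate value of gene g
in replicate r is

    v_gr = log2(base_g) + sum_f load_gf * sqrt(strength_f) * sigma_g * z_fr
           + sqrt(1 - sum_f load_gf^2 * strength_f) * sigma_g * e_gr

with z_fr one standard-normal draw per factor and replicate (shared by all
member genes — this is what creates replicate-level coordination) and e_gr
idiosyncratic.  sigma_g is chosen so that the *expected measured* sample CV
over the study's replicate count equals the programmed replicate_cv: the
log-normal sigma solving CV = sqrt(exp(sigma_ln^2) - 1) is divided by the
Gaussian small-sample factor c4(n), since the n-1-denominator sample SD at
n = 4 underestimates sigma by ~8% on average.  Two genes sharing one factor
with loadings l_g, l_h then have true replicate correlation
rho = sign(l_g l_h) * |l_g l_h| * strength.

Spot-level noise is independent across the redundant spots of a gene, which
is exactly why redundancy earns degrees of freedom downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coordination import pair_key

__all__ = ["LatentModule", "SimulationConfig", "SimulatedDataset", "simulate_dataset", "ground_truth_report", "load_ground_truth"]

DEFAULT_CONDITIONS = ["unstimulated", "18/1 2h", "18/1 5h", "90/5 2h", "90/5 5h"]


@dataclass(frozen=True)
class LatentModule:
    """A latent replicate-level factor shared by a group of genes.

    ``loadings`` maps member gene ids to values in [-1, 1]; ``strength`` in
    [0, 1] is the fraction of a member's replicate variance explained at
    |loading| = 1.  The induced true correlation between members g and h is
    loading_g * loading_h * strength.
    """

    name: str
    loadings: dict[str, float]
    strength: float

    def __post_init__(self):
        if not 0 <= self.strength <= 1:
            raise ValueError("factor strength must be in [0, 1]")
        for g, l in self.loadings.items():
            if not -1 <= l <= 1:
                raise ValueError(f"loading of {g!r} outside [-1, 1]")


@dataclass
class SimulationConfig:
    """Design of a synthetic dataset; defaults mirror the emulated study:
    5 conditions x 4 biological replicates, redundancy mostly 1 with a tail
    up to 28 spots, ~5-15% replicate CVs, scanner-scale intensities."""

    n_genes: int = 100
    conditions: list[str] = field(default_factory=lambda: list(DEFAULT_CONDITIONS))
    replicates: int = 4
    redundancy_max: int = 28
    redundancy_geom_p: float = 0.55  # truncated geometric over 1..redundancy_max
    redundancy: object = None  # optional per-gene override (int or length-n array)
    base_level_log2_mean: float = 0.0  # log2 of expression relative to array median
    base_level_log2_sd: float = 1.5
    base_level_log2: object = None  # optional per-gene override of the drawn levels
    replicate_cv: float = 10.0  # percent; scalar or per-gene array
    modules: list[LatentModule] = field(default_factory=list)
    spot_noise_cv: float = 3.0  # percent, independent per spot
    intensity_scale: float = 2000.0  # foreground counts at relative level 1
    background_mean: float = 100.0
    background_cv: float = 20.0  # percent
    fraction_control: float = 0.02
    fraction_corrupted: float = 0.02
    fraction_low_signal: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in ("fraction_control", "fraction_corrupted", "fraction_low_signal"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if np.any(np.asarray(self.replicate_cv) < 0) or self.spot_noise_cv < 0:
            raise ValueError("CVs must be >= 0")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates")


@dataclass
class SimulatedDataset:
    """Raw spot table plus the ground truth it was generated from."""

    raw: pd.DataFrame
    truth_genes: pd.DataFrame  # gene, base_level, replicate_cv, redundancy
    truth_pairs: pd.DataFrame  # gene_a, gene_b, rho_true, sign
    truth_spots: pd.DataFrame  # spot_id, label in {valid, control, corrupted, low_signal}
    config: SimulationConfig


def _c4(n: int) -> float:
    """E[sample SD]/sigma for n Gaussian draws (n-1 denominator)."""
    return math.sqrt(2.0 / (n - 1)) * math.gamma(n / 2) / math.gamma((n - 1) / 2)


def _sigma_log2(cv_percent: float, replicates: int) -> float:
    """Log2-scale SD whose expected measured sample CV equals cv_percent."""
    cv = cv_percent / 100.0
    if cv == 0:
        return 0.0
    sigma_ln = math.sqrt(math.log1p(cv * cv))
    return sigma_ln / math.log(2) / _c4(replicates)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a raw spot table with known levels, CVs and pair correlations.

    Deterministic for a fixed config + seed.  Raises a config error when a
    gene's factor loadings claim more variance than its total
    (sum of loading^2 * strength > 1).
    """
    rng = np.random.default_rng(config.seed)
    n, n_rep = config.n_genes, config.replicates
    genes = [f"G{i:04d}" for i in range(1, n + 1)]
    gene_idx = {g: i for i, g in enumerate(genes)}

    # per-gene design
    base_log2 = rng.normal(config.base_level_log2_mean, config.base_level_log2_sd, n)
    if config.base_level_log2 is not None:
        base_log2 = np.broadcast_to(
            np.asarray(config.base_level_log2, dtype=float), (n,)
        ).copy()
    cv = np.broadcast_to(np.asarray(config.replicate_cv, dtype=float), (n,)).copy()
    sigma = np.array([_sigma_log2(c, n_rep) for c in cv])
    redundancy = 1 + (rng.geometric(config.redundancy_geom_p, n) - 1) % config.redundancy_max
    if config.redundancy is not None:
        redundancy = np.broadcast_to(np.asarray(config.redundancy, dtype=int), (n,)).copy()
        if redundancy.min() < 1 or redundancy.max() > config.redundancy_max:
            raise ValueError("redundancy override outside 1..redundancy_max")

    # factor structure
    load = np.zeros((n, len(config.modules)))
    for f, mod in enumerate(config.modules):
        for g, l in mod.loadings.items():
            if g not in gene_idx:
                raise ValueError(f"module {mod.name!r} references unknown gene {g!r}")
            load[gene_idx[g], f] = l * math.sqrt(mod.strength)
    explained = (load**2).sum(axis=1)
    if np.any(explained > 1 + 1e-12):
        bad = genes[int(np.argmax(explained))]
        raise ValueError(f"factor variance exceeds total for gene {bad!r}")
    idio = np.sqrt(np.clip(1.0 - explained, 0.0, None))

    rows = []
    spot_ids: list[str] = []
    spot_gene: list[str] = []
    for g, r_g in zip(genes, redundancy):
        for k in range(1, int(r_g) + 1):
            spot_ids.append(f"{g}_s{k}")
            spot_gene.append(g)
    n_spots = len(spot_ids)
    sigma_spot = _sigma_log2(config.spot_noise_cv, n_rep) * _c4(n_rep)  # raw scale, no n-bias need
    bg_shape = None
    if config.background_cv > 0:
        bg_shape = 1.0 / (config.background_cv / 100.0) ** 2

    spot_of_gene: dict[str, list[str]] = {}
    for sid, g in zip(spot_ids, spot_gene):
        spot_of_gene.setdefault(g, []).append(sid)

    for cond in config.conditions:
        z = rng.standard_normal((len(config.modules), n_rep))
        e = rng.standard_normal((n, n_rep))
        v_rep = base_log2[:, None] + sigma[:, None] * (load @ z + idio[:, None] * e)
        for g in genes:
            gi = gene_idx[g]
            for sid in spot_of_gene[g]:
                spot_noise = sigma_spot * rng.standard_normal(n_rep)
                v_spot = v_rep[gi] + spot_noise
                fg_signal = config.intensity_scale * np.power(2.0, v_spot)
                if bg_shape is not None:
                    bg = rng.gamma(bg_shape, config.background_mean / bg_shape, n_rep)
                else:
                    bg = np.full(n_rep, config.background_mean)
                for r in range(n_rep):
                    rows.append(
                        (sid, g, cond, r + 1, fg_signal[r] + bg[r], bg[r], False, False)
                    )

    raw = pd.DataFrame(
        rows,
        columns=[
            "spot_id",
            "transcript_id",
            "condition",
            "replicate",
            "foreground",
            "background",
            "is_control",
            "is_corrupted",
        ],
    )

    # inject filter-test spots: choose disjoint spot sets per defect class
    labels = pd.Series("valid", index=pd.Index(spot_ids, name="spot_id"))
    perm = rng.permutation(n_spots)
    n_ctrl = int(round(config.fraction_control * n_spots))
    n_corr = int(round(config.fraction_corrupted * n_spots))
    n_low = int(round(config.fraction_low_signal * n_spots))
    ctrl_set = {spot_ids[i] for i in perm[:n_ctrl]}
    corr_set = {spot_ids[i] for i in perm[n_ctrl : n_ctrl + n_corr]}
    low_set = {spot_ids[i] for i in perm[n_ctrl + n_corr : n_ctrl + n_corr + n_low]}
    labels[list(ctrl_set)] = "control"
    labels[list(corr_set)] = "corrupted"
    labels[list(low_set)] = "low_signal"

    raw.loc[raw["spot_id"].isin(ctrl_set), "is_control"] = True
    n_samples = len(config.conditions) * n_rep
    for sid in corr_set:
        # corruption hits one random sample of the spot
        idx = raw.index[raw["spot_id"] == sid]
        raw.loc[idx[rng.integers(0, n_samples)], "is_corrupted"] = True
    for sid in low_set:
        # force foreground below twice background in one random sample
        idx = raw.index[raw["spot_id"] == sid]
        j = idx[rng.integers(0, n_samples)]
        raw.loc[j, "foreground"] = 1.5 * raw.loc[j, "background"]

    truth_genes = pd.DataFrame(
        {
            "gene": genes,
            "base_level": np.power(2.0, base_log2),
            "replicate_cv": cv,
            "redundancy": redundancy.astype(int),
        }
    )

    pair_rows = {}
    for mod in config.modules:
        members = sorted(mod.loadings)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                rho = mod.loadings[a] * mod.loadings[b] * mod.strength
                key = pair_key(a, b)
                pair_rows[key] = pair_rows.get(key, 0.0) + rho
    truth_pairs = pd.DataFrame(
        [
            {"gene_a": a, "gene_b": b, "rho_true": rho, "sign": "+" if rho > 0 else "-"}
            for (a, b), rho in sorted(pair_rows.items())
        ],
        columns=["gene_a", "gene_b", "rho_true", "sign"],
    )

    truth_spots = labels.rename("label").reset_index()
    return SimulatedDataset(
        raw=raw,
        truth_genes=truth_genes,
        truth_pairs=truth_pairs,
        truth_spots=truth_spots,
        config=config,
    )


def ground_truth_report(dataset: SimulatedDataset, outdir) -> dict[str, str]:
    """Write machine-readable truth tables aligned with pipeline outputs.

    Returns a manifest mapping table name -> file path; tables round-trip
    through :func:`load_ground_truth`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (
        ("genes", dataset.truth_genes),
        ("pairs", dataset.truth_pairs),
        ("spots", dataset.truth_spots),
    ):
        p = outdir / f"truth_{name}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        paths[name] = str(p)
    meta = outdir / "truth_meta.json"
    with open(meta, "w") as fh:
        json.dump(
            {
                "n_genes": dataset.config.n_genes,
                "conditions": dataset.config.conditions,
                "replicates": dataset.config.replicates,
                "seed": dataset.config.seed,
            },
            fh,
            indent=2,
        )
    paths["meta"] = str(meta)
    return paths


def load_ground_truth(outdir) -> dict[str, pd.DataFrame]:
    outdir = Path(outdir)
    return {
        name: pd.read_csv(outdir / f"truth_{name}.tsv", sep="\t")
        for name in ("genes", "pairs", "spots")
    }
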