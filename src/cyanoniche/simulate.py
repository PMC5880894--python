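"""Synthetic study generator: tree, sequences, environment, counts, truth.

The generative model is logistic-normal-multinomial so that clr-scale
analyses are correctly specified: per-sample linear predictors (intercepts,
environmental responses, latent factors, noise) pass through a softmax and
a multinomial draw at a log-normal depth. Niche coefficients are drawn from
a Gaussian process over taxa whose covariance decays with pairwise genetic
distance under a configurable kernel, and a subset of background taxa gets
planted conditionally-rare bursts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np

from .datamodel import (
    CountTable,
    DataError,
    EnvMatrix,
    SequenceSet,
    write_count_table,
    write_env_table,
    write_fasta,
)
from .decay import pairwise_distance_matrix

logger = logging.getLogger(__name__)

_BASES = "ACGT"

ENV_UNITS = {
    "PP": "ug/L",
    "PN": "mg/L",
    "DP": "ug/L",
    "DN": "mg/L",
    "precipitation": "mm",
    "temperature": "C",
    "microcystin": "ug/L",
}


@dataclass
class GenusConfig:
    name: str
    prefix: str
    n_taxa: int
    target_max_pdist: float
    kernel: dict = field(default_factory=lambda: {"name": "exponential", "length_scale": 0.02})


@dataclass
class SimConfig:
    """Knobs for a complete synthetic study."""

    genera: list[GenusConfig] = field(
        default_factory=lambda: [
            GenusConfig("Dolichospermum", "D", 25, 0.05),
            GenusConfig("Microcystis", "M", 6, 0.01),
        ]
    )
    n_background_taxa: int = 60
    n_samples: int = 135
    seq_length: int = 250
    covariates: list[str] = field(
        default_factory=lambda: ["PP", "PN", "DP", "DN", "precipitation", "temperature", "microcystin"]
    )
    env_autocorr: float = 0.6
    niche_sigma: float = 1.0
    background_beta_scale: float = 0.3
    n_latent: int = 2
    latent_scale: float = 0.3
    taxon_noise_sd: float = 0.3
    depth_median: int = 5000
    depth_sigma: float = 0.4
    crt_fraction: float = 0.1
    crt_burst_magnitude: float = 500.0
    # ~2% of samples burst: rarer, taller bursts keep the series two-state
    # so the bimodality detector can recover the planted labels
    crt_burst_sample_fraction: float = 0.02
    crt_baseline_intercept: float = -3.0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        data = dict(data)
        genera = [GenusConfig(**g) for g in data.pop("genera", [])]
        cfg = cls(**data)
        if genera:
            cfg.genera = genera
        return cfg


@dataclass
class SimTruth:
    """Ground truth stored alongside generated data for recovery tests."""

    trees: dict[str, str]
    distances: dict[str, dict]
    beta0: dict[str, float]
    beta: dict[str, list[float]]
    loadings: dict[str, list[float]]
    niche_correlation: dict[str, dict]
    crt_taxa: list[str]
    genus_of: dict[str, str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def evaluate_kernel(kernel: Mapping, d: np.ndarray) -> np.ndarray:
    """Evaluate a named similarity kernel on distances.

    ``exponential``: exp(-d / length_scale). ``nonmonotone``: the
    exponential minus a Gaussian bump (decay, rebound, decay), giving a
    non-monotone similarity-vs-distance curve.
    """
    d = np.asarray(d, dtype=float)
    name = kernel.get("name", "exponential")
    if name == "exponential":
        return np.exp(-d / float(kernel.get("length_scale", 0.02)))
    if name == "nonmonotone":
        ell = float(kernel.get("length_scale", 0.05))
        center = float(kernel.get("bump_center", 0.01))
        width = float(kernel.get("bump_width", 0.006))
        amplitude = float(kernel.get("bump_amplitude", 0.5))
        return np.exp(-d / ell) - amplitude * np.exp(-((d - center) ** 2) / (2 * width**2))
    raise ValueError(f"unknown kernel {name!r}")


def kernel_matrix(kernel: Mapping, distances: np.ndarray, jitter: bool = True) -> np.ndarray:
    """Kernel evaluated on a distance matrix, corrected to be PSD.

    Negative eigenvalues are clipped to zero when ``jitter`` is true;
    otherwise a non-PSD matrix is an error.
    """
    k = evaluate_kernel(kernel, distances)
    k = (k + k.T) / 2.0
    eigval, eigvec = np.linalg.eigh(k)
    if eigval.min() < -1e-10 * max(1.0, eigval.max()):
        if not jitter:
            raise DataError(f"kernel matrix is not positive semidefinite (min eig {eigval.min():.3g})")
        logger.debug("clipping %d negative kernel eigenvalues", int((eigval < 0).sum()))
    eigval = np.clip(eigval, 0.0, None)
    return eigvec @ np.diag(eigval) @ eigvec.T


def _jc_p_from_branch(branch_length: float) -> float:
    return 0.75 * (1.0 - np.exp(-4.0 * branch_length / 3.0))


def _jc_branch_from_p(p: float) -> float:
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def simulate_tree_and_sequences(
    n_taxa: int,
    seq_length: int,
    target_max_pdist: float,
    seed: int,
    prefix: str = "T",
):
    """Pure-birth tree with sequences evolved by equal-rate substitution.

    Branch lengths are rescaled so the Jukes-Cantor expectation of the
    maximum pairwise p-distance matches ``target_max_pdist``. Returns
    (newick string, SequenceSet, realized p-distance DataFrame).
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng_py = random.Random(seed)
    rng = np.random.default_rng(seed)
    taxa = [f"{prefix}{i + 1:02d}" for i in range(n_taxa)]
    namespace = dendropy.TaxonNamespace(taxa)
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        taxon_namespace=namespace,
        rng=rng_py,
    )
    pdm = tree.phylogenetic_distance_matrix()
    max_path = max(
        pdm.path_edge_count(t1, t2) and pdm.distance(t1, t2)
        for i, t1 in enumerate(namespace)
        for t2 in list(namespace)[i + 1:]
    )
    if target_max_pdist > 0 and max_path > 0:
        scale = _jc_branch_from_p(target_max_pdist) / max_path
    else:
        scale = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale

    root_seq = rng.integers(0, 4, size=seq_length)

    def evolve_all(factor: float):
        sequences: dict[str, str] = {}

        def evolve(node, seq):
            b = (node.edge.length or 0.0) * factor
            if b > 0:
                p_sub = _jc_p_from_branch(b)
                mutate = rng.random(seq_length) < p_sub
                if mutate.any():
                    seq = seq.copy()
                    shifts = rng.integers(1, 4, size=int(mutate.sum()))
                    seq[mutate] = (seq[mutate] + shifts) % 4
            if node.is_leaf():
                sequences[node.taxon.label] = "".join(_BASES[b] for b in seq)
            else:
                for child in node.child_nodes():
                    evolve(child, seq)

        root = tree.seed_node
        for child in root.child_nodes():
            evolve(child, root_seq)
        if root.is_leaf():  # degenerate single-branch case
            sequences[root.taxon.label] = "".join(_BASES[b] for b in root_seq)
        return SequenceSet({t: sequences[t] for t in taxa})

    # realized max distance overshoots the longest-path expectation (it is a
    # max over all pairs); recalibrate the clock a few times against it
    factor = 1.0
    seqset = evolve_all(factor)
    distances = pairwise_distance_matrix(seqset)
    if target_max_pdist > 0:
        for _ in range(4):
            realized = float(distances.to_numpy().max())
            if realized == 0 or abs(realized - target_max_pdist) <= 0.2 * target_max_pdist:
                break
            factor *= target_max_pdist / realized
            seqset = evolve_all(factor)
            distances = pairwise_distance_matrix(seqset)
    newick = tree.as_string(schema="newick").strip()
    return newick, seqset, distances


def simulate_niche_coefficients(
    distances: np.ndarray,
    kernel: Mapping,
    n_covariates: int,
    seed: int,
    sigma: float = 1.0,
    jitter: bool = True,
):
    """Draw per-covariate niche coefficients from a GP over taxa.

    Each covariate's coefficient vector is N(0, sigma^2 K(d)). Returns
    (beta: taxa x covariates, implied true niche-correlation matrix).
    """
    rng = np.random.default_rng(seed)
    k = kernel_matrix(kernel, np.asarray(distances, dtype=float), jitter=jitter)
    n = k.shape[0]
    eigval, eigvec = np.linalg.eigh(k)
    eigval = np.clip(eigval, 0.0, None)
    factor = eigvec @ np.diag(np.sqrt(eigval))
    beta = sigma * (factor @ rng.standard_normal((n, n_covariates)))
    diag = np.sqrt(np.clip(np.diag(k), 1e-12, None))
    true_corr = k / np.outer(diag, diag)
    np.fill_diagonal(true_corr, 1.0)
    return beta, np.clip(true_corr, -1.0, 1.0)


def simulate_environment(cfg: SimConfig, seed: int) -> EnvMatrix:
    """Seasonal AR(1) covariate series, one per configured variable."""
    rng = np.random.default_rng(seed)
    n = cfg.n_samples
    t = np.arange(n)
    values = np.empty((n, len(cfg.covariates)))
    for k, name in enumerate(cfg.covariates):
        phase = rng.uniform(0, 2 * np.pi)
        seasonal = np.sin(2 * np.pi * t / 17.0 + phase)  # ~17 samples per season
        noise = np.empty(n)
        noise[0] = rng.standard_normal()
        for i in range(1, n):
            noise[i] = cfg.env_autocorr * noise[i - 1] + np.sqrt(
                1 - cfg.env_autocorr**2
            ) * rng.standard_normal()
        values[:, k] = seasonal + 0.8 * noise
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    units = {name: ENV_UNITS.get(name, "") for name in cfg.covariates}
    return EnvMatrix(sample_ids, list(cfg.covariates), values, units)


def simulate_counts(
    beta0: np.ndarray,
    beta: np.ndarray,
    x: np.ndarray,
    loadings: np.ndarray,
    cfg: SimConfig,
    seed: int,
    crt_taxa_idx: list[int] | None = None,
    taxon_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> CountTable:
    """Multinomial counts from a logistic-normal linear predictor.

    eta_ij = b0_j + x_i . b_j + z_i . l_j + taxon noise; planted CRT taxa
    get a log(burst) boost in a random fraction of samples; per-sample
    composition is the softmax of eta and counts are multinomial at a
    log-normal depth.
    """
    rng = np.random.default_rng(seed)
    n, p = x.shape
    d_taxa = beta.shape[0]
    if beta.shape[1] != p or beta0.shape[0] != d_taxa or loadings.shape[0] != d_taxa:
        raise DataError("inconsistent shapes in count simulation")
    z = rng.standard_normal((n, loadings.shape[1])) if loadings.shape[1] else np.zeros((n, 0))
    eta = beta0[None, :] + x @ beta.T + z @ loadings.T
    eta = eta + cfg.taxon_noise_sd * rng.standard_normal(eta.shape)
    for j in crt_taxa_idx or []:
        n_burst = max(1, round(cfg.crt_burst_sample_fraction * n))
        burst_samples = rng.choice(n, size=n_burst, replace=False)
        # two-state dynamics: burst samples sit at a common elevated level so
        # the series is genuinely bimodal rather than a graded gradient
        eta[burst_samples, j] = beta0[j] + np.log(cfg.crt_burst_magnitude)
    eta -= eta.max(axis=1, keepdims=True)
    comp = np.exp(eta)
    comp /= comp.sum(axis=1, keepdims=True)
    depths = np.maximum(
        100, np.round(np.exp(rng.normal(np.log(cfg.depth_median), cfg.depth_sigma, size=n)))
    ).astype(np.int64)
    counts = np.vstack([rng.multinomial(depths[i], comp[i]) for i in range(n)]).T
    taxon_ids = taxon_ids or [f"t{j + 1:03d}" for j in range(d_taxa)]
    sample_ids = sample_ids or [f"S{i + 1:03d}" for i in range(n)]
    return CountTable(list(taxon_ids), list(sample_ids), counts)


def _sample_metadata(n_samples: int) -> dict[str, dict[str, str]]:
    meta = {}
    for i in range(n_samples):
        year = 2006 + (i * 8) // n_samples
        month = 4 + (i % 8)
        meta[f"S{i + 1:03d}"] = {
            "date": f"{year:04d}-{month:02d}-15",
            "site": "littoral" if i % 2 == 0 else "pelagic",
        }
    return meta


def generate_study(cfg: SimConfig, out_dir: str | Path | None = None, force: bool = False):
    """Generate a full synthetic study and optionally write it to disk.

    Returns (CountTable, EnvMatrix, SequenceSet, SimTruth). On disk:
    counts.tsv, counts.meta.tsv, env.tsv, sequences.fasta, tree_<genus>.nwk,
    truth.json and manifest.json.
    """
    master = np.random.default_rng(cfg.seed)
    stage_seed = {
        name: int(master.integers(2**31))
        for name in ("trees", "beta", "env", "counts", "background")
    }

    trees: dict[str, str] = {}
    seqs: dict[str, str] = {}
    dist_frames = {}
    genus_of: dict[str, str] = {}
    focal_ids: list[str] = []
    beta_blocks = []
    true_corrs = {}
    for g_idx, genus in enumerate(cfg.genera):
        newick, seqset, distances = simulate_tree_and_sequences(
            genus.n_taxa,
            cfg.seq_length,
            genus.target_max_pdist,
            seed=stage_seed["trees"] + g_idx,
            prefix=genus.prefix,
        )
        trees[genus.name] = newick
        seqs.update(seqset.sequences)
        dist_frames[genus.name] = distances
        beta_g, corr_g = simulate_niche_coefficients(
            distances.to_numpy(),
            genus.kernel,
            len(cfg.covariates),
            seed=stage_seed["beta"] + g_idx,
            sigma=cfg.niche_sigma,
        )
        beta_blocks.append(beta_g)
        true_corrs[genus.name] = corr_g
        for t in distances.index:
            genus_of[t] = genus.name
            focal_ids.append(t)

    rng_bg = np.random.default_rng(stage_seed["background"])
    bg_ids = [f"B{i + 1:03d}" for i in range(cfg.n_background_taxa)]
    beta_bg = cfg.background_beta_scale * rng_bg.standard_normal(
        (cfg.n_background_taxa, len(cfg.covariates))
    )
    taxon_ids = focal_ids + bg_ids
    beta = np.vstack(beta_blocks + [beta_bg])
    d_total = len(taxon_ids)

    n_crt = max(1, round(cfg.crt_fraction * cfg.n_background_taxa))
    crt_local = rng_bg.choice(cfg.n_background_taxa, size=n_crt, replace=False)
    crt_idx = [len(focal_ids) + int(i) for i in sorted(crt_local)]
    crt_taxa = [taxon_ids[i] for i in crt_idx]

    beta0 = 0.5 * rng_bg.standard_normal(d_total)
    beta0[: len(focal_ids)] += 0.5  # focal genera are bloom-formers: higher baseline
    beta0[crt_idx] = cfg.crt_baseline_intercept
    loadings = cfg.latent_scale * rng_bg.standard_normal((d_total, cfg.n_latent))
    # planted CRT dynamics are burst-driven, not environment-driven: a strong
    # environmental response would mimic a seasonal taxon, not a rare one
    beta[crt_idx, :] = 0.0
    loadings[crt_idx, :] = 0.0

    env = simulate_environment(cfg, stage_seed["env"])
    x = (env.values - env.values.mean(axis=0)) / env.values.std(axis=0, ddof=1)
    ct = simulate_counts(
        beta0,
        beta,
        x,
        loadings,
        cfg,
        seed=stage_seed["counts"],
        crt_taxa_idx=crt_idx,
        taxon_ids=taxon_ids,
        sample_ids=list(env.sample_ids),
    )
    ct.sample_meta.update(_sample_metadata(cfg.n_samples))

    truth = SimTruth(
        trees=trees,
        distances={g: df.to_dict() for g, df in dist_frames.items()},
        beta0={t: float(b) for t, b in zip(taxon_ids, beta0)},
        beta={t: [float(v) for v in row] for t, row in zip(taxon_ids, beta)},
        loadings={t: [float(v) for v in row] for t, row in zip(taxon_ids, loadings)},
        niche_correlation={
            g: {a: {b: float(c[i, j]) for j, b in enumerate(dist_frames[g].index)}
                for i, a in enumerate(dist_frames[g].index)}
            for g, c in true_corrs.items()
        },
        crt_taxa=crt_taxa,
        genus_of=genus_of,
    )
    seqset_all = SequenceSet(seqs, uniform_length=True)

    if out_dir is not None:
        out = Path(out_dir)
        if out.exists() and any(out.iterdir()) and not force:
            raise FileExistsError(f"output directory {out} exists; use force to overwrite")
        out.mkdir(parents=True, exist_ok=True)
        write_count_table(ct, out / "counts.tsv")
        with open(out / "counts.meta.tsv", "w") as fh:
            fh.write("sample_id\tdate\tsite\n")
            for sid in ct.sample_ids:
                m = ct.sample_meta.get(sid, {})
                fh.write(f"{sid}\t{m.get('date', '')}\t{m.get('site', '')}\n")
        write_env_table(env, out / "env.tsv")
        write_fasta(seqset_all, out / "sequences.fasta")
        for genus, newick in trees.items():
            (out / f"tree_{genus}.nwk").write_text(newick + "\n")
        (out / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))
        manifest = {"seed": cfg.seed, "config_hash": cfg.config_hash(), "config": cfg.to_dict()}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return ct, env, seqset_all, truth
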