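"""Synthetic comparative datasets with the covariance structure the model assumes.

Generates Yule (pure-birth) trees rescaled to unit height, predictors on
their natural scales, and a log-effort response

    y = X beta + eps,   Cov(eps) = sigma^2 (C_lambda + sum_k gamma_k D_k)

drawn exactly through the triangular factor of the model covariance. The
defaults emulate the study conditions the package targets: 36 species, a
1,000-tree ensemble, full phylogenetic signal (lambda = 1), quality
variance ratios (22.33, 0.11, 0.18), and slopes on the raw predictor
scales of 1.98 (kinship) and -0.015 (per % male helpers), with null group
size and %-nests-helped effects. Everything flows from one integer seed;
identical configs produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data import SpeciesRecord, write_species_csv
from .phylo import Phylogeny, read_newick, vcv
from .pgls import build_covariance

__all__ = ["SyntheticConfig", "simulate_tree", "simulate_dataset",
           "make_fixture_suite", "SimulatedDataset"]


@dataclass
class SyntheticConfig:
    """All parameters of a generated dataset.

    ``beta`` is on the raw predictor scales (intercept, kinship r, helper
    sex ratio in % male, mean group size, % nests helped), producing log
    effort; ``gamma`` are the per-quality-class variance ratios to the
    phylogenetic scale ``sigma2``.
    """

    n_species: int = 36
    beta: tuple[float, ...] = (3.32, 1.98, -0.015, 0.0, 0.0)
    lam: float = 1.0
    sigma2: float = 0.05
    gamma: tuple[float, float, float] = (22.33, 0.11, 0.18)
    quality_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    n_trees: int = 1000
    seed: int = 0
    # predictor distributions (uniform ranges unless noted)
    kinship_range: tuple[float, float] = (0.0, 0.5)
    sexratio_range: tuple[float, float] = (0.0, 100.0)
    group_size_exp_scale: float = 2.5      # group size = 2 + Exponential(scale)
    pct_helped_range: tuple[float, float] = (5.0, 100.0)
    epp_range: tuple[float, float] = (0.0, 10.0)
    brownian_predictors: bool = False      # add phylogenetic signal to predictors

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if any(g < 0 for g in self.gamma):
            raise ValueError("gamma components must be non-negative")
        if abs(sum(self.quality_probs) - 1.0) > 1e-9:
            raise ValueError("quality_probs must sum to 1")
        if len(self.beta) != 5:
            raise ValueError("beta must have 5 entries (intercept + 4 predictors)")


def simulate_tree(n_species: int, seed=None) -> Phylogeny:
    """Yule (pure-birth) tree with unit birth rate, rescaled to unit height.

    Tips are labelled sp1..spn in birth order. ``seed`` may be an int or a
    numpy Generator; a given seed always yields the same Newick string.
    """
    if n_species < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # children[i]: (left, right) node ids or None for active/tip nodes
    birth = {0: 0.0, 1: 0.0, 2: 0.0}   # node 0 = root, splits at t=0
    children: dict[int, tuple[int, int] | None] = {0: (1, 2), 1: None, 2: None}
    active = [1, 2]
    t = 0.0
    nxt = 3
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        idx = rng.integers(len(active))
        parent = active[idx]
        a, b = nxt, nxt + 1
        nxt += 2
        birth[a] = birth[b] = t
        children[a] = children[b] = None
        children[parent] = (a, b)
        active[idx] = a
        active.append(b)
    t_end = t + rng.exponential(1.0 / n_species)

    labels = {node: f"sp{i + 1}" for i, node in enumerate(active)}
    height = t_end if t_end > 0 else 1.0

    def nwk(node: int) -> str:
        if children[node] is None:
            length = (t_end - birth[node]) / height
            return f"{labels[node]}:{length:.10f}"
        a, b = children[node]
        length = (birth[a] - birth[node]) / height  # a, b born together
        return f"({nwk(a)},{nwk(b)}):{length:.10f}"

    a, b = children[0]
    newick = f"({nwk(a)},{nwk(b)});"
    return read_newick(newick)[0]


@dataclass
class SimulatedDataset:
    records: list[SpeciesRecord]
    trees: list[Phylogeny]
    truth: dict
    X_raw: np.ndarray
    y: np.ndarray
    quality: np.ndarray


def simulate_dataset(cfg: SyntheticConfig) -> SimulatedDataset:
    """Draw one comparative dataset (and its tree ensemble) from the model.

    Residuals are generated with the first tree as the true phylogeny; the
    remaining trees play the role of the equiprobable ensemble expressing
    phylogenetic uncertainty around it. ``effort_pct = exp(y)`` is always
    positive, so the pipeline's log transform is safe on synthetic data.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_species
    trees = [simulate_tree(n, rng) for _ in range(cfg.n_trees)]
    taxa = [f"sp{i + 1}" for i in range(n)]
    C = vcv(trees[0], taxa)

    kin = rng.uniform(*cfg.kinship_range, size=n)
    sex = rng.uniform(*cfg.sexratio_range, size=n)
    grp = 2.0 + rng.exponential(cfg.group_size_exp_scale, size=n)
    hel = rng.uniform(*cfg.pct_helped_range, size=n)
    if cfg.brownian_predictors:
        # add tree-correlated wiggle scaled to each predictor's spread
        L = np.linalg.cholesky(C.C + 1e-12 * np.eye(n))
        for arr in (kin, sex, grp, hel):
            arr += 0.25 * arr.std(ddof=0) * (L @ rng.standard_normal(n))
        kin = np.clip(kin, 0.0, 0.5)
        sex = np.clip(sex, 0.0, 100.0)
        grp = np.maximum(grp, 2.0)
        hel = np.clip(hel, 1.0, 100.0)

    quality = rng.choice([1, 2, 3], size=n, p=cfg.quality_probs)
    X = np.column_stack([np.ones(n), kin, sex, grp, hel])
    V = cfg.sigma2 * build_covariance(C, cfg.lam, cfg.gamma, quality)
    L = np.linalg.cholesky(V)
    eps = L @ rng.standard_normal(n)
    y = X @ np.asarray(cfg.beta) + eps
    effort = np.exp(y)
    epp = rng.uniform(*cfg.epp_range, size=n)

    records = [SpeciesRecord(
        species_id=taxa[i], effort_pct=float(effort[i]), kinship_r=float(kin[i]),
        sexratio_pct_male=float(sex[i]), group_size=float(grp[i]),
        pct_nests_helped=float(hel[i]), quality=int(quality[i]),
        epp_rate=float(epp[i])) for i in range(n)]

    truth = asdict(cfg)
    truth["quality_counts"] = {str(k): int((quality == k).sum()) for k in (1, 2, 3)}
    return SimulatedDataset(records=records, trees=trees, truth=truth,
                            X_raw=X, y=y, quality=quality)


def write_dataset(ds: SimulatedDataset, out_dir) -> dict[str, Path]:
    """Write species CSV, multi-Newick tree file and ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"species": out / "species.csv", "trees": out / "trees.nwk",
             "truth": out / "truth.json"}
    write_species_csv(ds.records, paths["species"])
    with open(paths["trees"], "w", encoding="utf-8") as fh:
        for tree in ds.trees:
            fh.write(tree.newick() + "\n")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(ds.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def make_fixture_suite(out_dir, seed: int = 0, overwrite: bool = False) -> dict[str, Path]:
    """Write small hand-checkable fixtures used by the test suite.

    Includes the worked 3-taxon tree ((A:1,B:1):1,C:2); whose unnormalized
    covariance is [[2,1,0],[1,2,0],[0,0,2]], tiny 3/5/10-species datasets,
    and a sex-share vector for the signed-rank test.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def dest(name: str) -> Path:
        p = out / name
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True to replace it")
        return p

    p = dest("worked_tree.nwk")
    p.write_text("((A:1,B:1):1,C:2);\n", encoding="utf-8")
    paths["worked_tree"] = p

    for n in (3, 5, 10):
        cfg = SyntheticConfig(n_species=n, n_trees=2, seed=seed + n,
                              gamma=(0.5, 0.1, 0.0), sigma2=0.1)
        sub = out / f"species{n}"
        if sub.exists() and not overwrite:
            raise FileExistsError(f"{sub} exists; pass overwrite=True to replace it")
        ds = simulate_dataset(cfg)
        paths[f"species{n}"] = write_dataset(ds, sub)["species"].parent

    p = dest("sex_shares.csv")
    rng = np.random.default_rng(seed)
    shares = np.round(np.clip(rng.normal(0.55, 0.1, size=12), 0.05, 0.95), 4)
    p.write_text("share_female\n" + "\n".join(str(s) for s in shares) + "\n",
                 encoding="utf-8")
    paths["sex_shares"] = p
    return paths
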