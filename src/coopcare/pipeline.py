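"""End-to-end comparative analysis: filters, ensemble PGLS fits, reports.

Reproducible orchestration of the helper-effort analysis: the full model
(log helper effort on z-scored kinship, helper sex ratio, group size and
% nests helped, with quality variance components, fitted across a tree
ensemble), the conservative re-fit after the stricter exclusions, the
lambda-only bivariate checks (helper sex ratio against % nests helped and
against kinship), and exact one-sample signed-rank tests of whether
females contribute more than half of total care.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from . import data as cd
from .data import SpeciesRecord, apply_filters, standardize_predictors, transform_response
from .pgls import (EnsembleFit, FitOptions, PGLSVCModel, ensemble_fit)
from .phylo import Phylogeny, read_newick, vcv

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis",
           "run_conservative_analysis", "wilcoxon_one_tailed", "WilcoxonResult"]

logger = logging.getLogger(__name__)

#: Above this sample size the exact 2^n signed-rank null is replaced by the
#: normal approximation with continuity and tie corrections.
EXACT_WILCOXON_LIMIT = 25


# ---------------------------------------------------------------------------
# Exact one-tailed one-sample Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    n: int
    statistic: float   # W+, sum of ranks of positive deviations
    p_value: float
    method: str


def _signed_rank_tail(ranks2: np.ndarray, w2_obs: int) -> float:
    """P(W+ >= obs) under the 2^n sign-flip null, via subset-sum counting.

    ``ranks2`` are the (mid)ranks doubled so ties give integers. The count
    of sign assignments reaching each doubled rank-sum is built by dynamic
    programming; this is an exact enumeration of all 2^n equally likely
    patterns without materializing them.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        counts[r:] = counts[r:] + counts[:total + 1 - r]
    return float(counts[w2_obs:].sum() / 2.0 ** len(ranks2))


def wilcoxon_one_tailed(values, mu: float = 0.5) -> WilcoxonResult:
    """One-tailed one-sample signed-rank test of 'values greater than mu'.

    Values exactly equal to ``mu`` are dropped before ranking; tied
    absolute deviations receive midranks and the exact null (all 2^n sign
    assignments, conditional on the observed ranks) is still used for
    n <= 25. Larger samples use the normal approximation with tie and
    continuity corrections.
    """
    v = np.asarray(values, dtype=float).ravel()
    d = v - mu
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all values equal the hypothesized center; no information")
    absd = np.abs(d)
    ranks = stats.rankdata(absd)            # midranks
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_LIMIT:
        ranks2 = np.rint(2.0 * ranks).astype(int)
        w2 = int(np.rint(2.0 * w_plus))
        p = _signed_rank_tail(ranks2, w2)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(absd, return_counts=True)
        var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        z = (w_plus - mean - 0.5) / np.sqrt(var)
        p = float(stats.norm.sf(z))
        method = "normal_approx"
    return WilcoxonResult(n=n, statistic=w_plus, p_value=p, method=method)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    criterion: str = "reml"
    n_starts: int = 8
    aggregation: str = "mean"
    seed: int = 0
    epp_threshold: float = cd.DEFAULT_EPP_THRESHOLD
    compute_r2: bool = True
    aux_quality_variance: bool = False   # bivariate checks default to plain PGLS
    min_quality_class_size: int = 2

    def fit_options(self) -> FitOptions:
        return FitOptions(criterion=self.criterion, n_starts=self.n_starts,
                          compute_r2=self.compute_r2, seed=self.seed)


@dataclass
class AnalysisReport:
    full_fit: EnsembleFit
    no_quality_fit: EnsembleFit
    unstandardized_fit: EnsembleFit
    conservative_fit: EnsembleFit | None
    auxiliary_fits: dict[str, EnsembleFit]
    wilcoxon: dict[str, WilcoxonResult]
    exclusions: list[dict]
    n_species: int
    n_trees: int
    provenance: dict

    def to_dict(self) -> dict:
        def ens(e: EnsembleFit | None):
            if e is None:
                return None
            return {"aggregate": e.aggregate, "n_trees_ok": len(e.fits),
                    "n_trees_failed": len(e.failures),
                    "aggregation": e.aggregation}
        return {
            "n_species": self.n_species,
            "n_trees": self.n_trees,
            "full_fit": ens(self.full_fit),
            "no_quality_fit": ens(self.no_quality_fit),
            "unstandardized_fit": ens(self.unstandardized_fit),
            "conservative_fit": ens(self.conservative_fit),
            "auxiliary_fits": {k: ens(v) for k, v in self.auxiliary_fits.items()},
            "wilcoxon": {k: {"n": w.n, "statistic": w.statistic,
                             "p_value": w.p_value, "method": w.method}
                         for k, w in self.wilcoxon.items()},
            "exclusions": self.exclusions,
            "provenance": self.provenance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def table_tsv(self, path=None) -> str:
        """Coefficient table in the standardized-coefficients layout."""
        agg = self.full_fit.aggregate
        lines = ["term\tcoefficient\tse\tt\tp"]
        for name, b, s, t, p in zip(agg["names"], agg["beta"], agg["se"],
                                    agg["t"], agg["p_values"]):
            lines.append(f"{name}\t{b:.4f}\t{s:.4f}\t{t:.4f}\t{p:.4g}")
        lines.append("")
        lines.append("variance_component\testimate\tse")
        lines.append(f"lambda\t{agg['lambda']:.4f}\t{agg['lambda_se']:.4f}")
        for k in ("1", "2", "3"):
            lines.append(f"data_quality_{k}\t{agg['gamma'][k]:.4f}\t{agg['gamma_se'][k]:.4f}")
        if agg.get("r2") is not None:
            lines.append("")
            lines.append(f"r2\t{agg['r2']:.4f}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _load_records(data_src) -> list[SpeciesRecord]:
    if isinstance(data_src, (str, Path)):
        return cd.read_species_csv(data_src)
    return list(data_src)


def _load_trees(trees_src) -> list[Phylogeny]:
    if isinstance(trees_src, (str, Path)):
        return read_newick(trees_src)
    return list(trees_src)


def _check_coverage(records: Sequence[SpeciesRecord], trees: Sequence[Phylogeny]) -> None:
    names = [r.species_id for r in records]
    for i, tree in enumerate(trees):
        missing = sorted(set(n.replace(" ", "_") for n in names) - set(tree.tips))
        if missing:
            raise ValueError(f"tree {i} is missing species {missing}")


def _quality_guard(records: Sequence[SpeciesRecord], min_size: int) -> None:
    counts: dict[int, int] = {}
    for r in records:
        counts[r.quality] = counts.get(r.quality, 0) + 1
    if counts and max(counts.values()) == 1:
        raise ValueError(
            "every data-quality class contains a single species; the quality "
            "variance components are not estimable")
    small = {k: v for k, v in counts.items() if v < min_size}
    if small:
        logger.warning("quality classes with fewer than %d species: %s", min_size, small)


def _ensemble(y, X, names, quality, records, trees, options, aggregation,
              free_gamma=True):
    taxa = [r.species_id for r in records]

    def builder(tree: Phylogeny) -> PGLSVCModel:
        return PGLSVCModel(y=y, X=X, C=vcv(tree, taxa), quality=quality, names=names)

    return ensemble_fit(builder, trees, options, aggregation=aggregation,
                        free_gamma=free_gamma)


def _file_sha(path) -> str | None:
    try:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()
    except (OSError, TypeError):
        return None


def run_full_analysis(data_src, trees_src, config: AnalysisConfig | None = None,
                      sex_shares: dict[str, Sequence[float]] | None = None,
                      mode: str = "full") -> AnalysisReport:
    """Run the complete analysis and return a machine-readable report.

    ``data_src`` is a species CSV path or a sequence of SpeciesRecord;
    ``trees_src`` a Newick path or list of Phylogeny. ``sex_shares``
    optionally maps labels (e.g. "helpers", "breeders") to vectors of the
    proportion of care contributed by females, tested against 0.5.
    """
    cfg = config or AnalysisConfig()
    records_all = _load_records(data_src)
    trees = _load_trees(trees_src)

    filtered = apply_filters(records_all, mode=mode, epp_threshold_full=cfg.epp_threshold)
    records = filtered.records
    if not records:
        raise ValueError("no species survive the exclusion filters")
    if len(records) < 8:
        raise ValueError(f"only {len(records)} species after filtering; too few to fit")
    _check_coverage(records, trees)
    _quality_guard(records, cfg.min_quality_class_size)

    quality = np.array([r.quality for r in records])
    y_raw = transform_response(np.array([r.effort_pct for r in records]))
    std = standardize_predictors(records)
    sd_y = float(np.std(y_raw, ddof=1))
    y_std = (y_raw - y_raw.mean()) / sd_y
    names = std.columns
    opts = cfg.fit_options()

    logger.info("fitting full model: %d species, %d trees", len(records), len(trees))
    full_fit = _ensemble(y_std, std.X, names, quality, records, trees,
                         opts, cfg.aggregation)
    no_quality = _ensemble(y_std, std.X, names, quality, records, trees,
                           opts, cfg.aggregation, free_gamma=False)
    unstd_X = np.column_stack(
        [np.ones(len(records))] +
        [[getattr(r, c) for r in records] for c in cd.PREDICTOR_COLUMNS])
    unstd = _ensemble(y_raw, unstd_X, names, quality, records, trees,
                      opts, cfg.aggregation)

    # bivariate checks: helper sex ratio vs ecological constraint and kinship
    aux: dict[str, EnsembleFit] = {}
    aux_opts = cfg.fit_options()
    sex = np.array([r.sexratio_pct_male for r in records])
    for label, resp in (("pct_helped_on_sexratio",
                         np.array([r.pct_nests_helped for r in records])),
                        ("kinship_on_sexratio",
                         np.array([r.kinship_r for r in records]))):
        Xb = np.column_stack([np.ones(len(records)), sex])
        aux[label] = _ensemble(resp, Xb, ("intercept", "sexratio_pct_male"),
                               quality, records, trees, aux_opts, cfg.aggregation,
                               free_gamma=cfg.aux_quality_variance)

    wil = {}
    for label, vals in (sex_shares or {}).items():
        wil[label] = wilcoxon_one_tailed(vals, mu=0.5)

    conservative = None
    if mode == "full":
        cons_filtered = apply_filters(records_all, mode="conservative",
                                      epp_threshold_full=cfg.epp_threshold)
        dropped = {e["species_id"] for e in cons_filtered.exclusions
                   if e["rule"] != "epp_unknown_retained"}
        if dropped and len(cons_filtered.records) >= 8:
            conservative = _fit_records(cons_filtered.records, trees, cfg)
        elif not dropped:
            conservative = full_fit   # filter is a no-op

    provenance = {
        "seed": cfg.seed, "criterion": cfg.criterion,
        "aggregation": cfg.aggregation, "mode": mode,
        "epp_threshold": cfg.epp_threshold,
        "data_sha256": _file_sha(data_src) if isinstance(data_src, (str, Path)) else None,
        "trees_sha256": _file_sha(trees_src) if isinstance(trees_src, (str, Path)) else None,
        "response_sd": sd_y,
        "predictor_means": std.means.tolist(),
        "predictor_sds": std.sds.tolist(),
    }
    return AnalysisReport(
        full_fit=full_fit, no_quality_fit=no_quality, unstandardized_fit=unstd,
        conservative_fit=conservative, auxiliary_fits=aux, wilcoxon=wil,
        exclusions=filtered.exclusions, n_species=len(records),
        n_trees=len(trees), provenance=provenance)


def _fit_records(records, trees, cfg: AnalysisConfig) -> EnsembleFit:
    _check_coverage(records, trees)
    _quality_guard(records, cfg.min_quality_class_size)
    quality = np.array([r.quality for r in records])
    y_raw = transform_response(np.array([r.effort_pct for r in records]))
    std = standardize_predictors(records)
    y_std = (y_raw - y_raw.mean()) / float(np.std(y_raw, ddof=1))
    return _ensemble(y_std, std.X, std.columns, quality, records, trees,
                     cfg.fit_options(), cfg.aggregation)


def run_conservative_analysis(data_src, trees_src,
                              config: AnalysisConfig | None = None) -> EnsembleFit:
    """Re-fit after the conservative exclusions (stricter benchmark rules)."""
    cfg = config or AnalysisConfig()
    records_all = _load_records(data_src)
    trees = _load_trees(trees_src)
    filtered = apply_filters(records_all, mode="conservative",
                             epp_threshold_full=cfg.epp_threshold)
    if not filtered.records:
        raise ValueError("conservative filters removed every species")
    return _fit_records(filtered.records, trees, cfg)
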