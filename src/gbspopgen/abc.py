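"""Approximate Bayesian computation: summary statistics, reference
tables, rejection, regression-adjusted posteriors, scenario choice, and
accuracy metrics.

The summary-statistic vector is assembled from per-locus quantities
computed on within-group sample allele frequencies:

* per group: proportion of loci with null gene diversity, and mean gene
  diversity across polymorphic loci;
* per group pair: proportion of loci with null Nei's standard distance,
  and variance across loci of the non-null distances;
* per (admixed, parent1, parent2) trio: proportion of loci with null
  admixture estimates, mean and variance of the non-null estimates, and
  the mean across all (defined) loci.

"Null" means exactly zero.  Admixture estimates with equal parental
frequencies are undefined and excluded from all aggregates (they are
neither null nor non-null); infinite Nei distances (fixed for opposite
alleles) are capped at a configurable constant.

Estimation follows the classic rejection + weighted local linear
regression recipe: accept the closest fraction of standardized
statistic vectors by Euclidean distance, weight them with an
Epanechnikov kernel, regress a bound-respecting transform of each
parameter on the statistics, and correct the accepted draws to the
observed vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .priors import PriorSet
from .scenarios import DemographicScenario
from .simulate import simulate_counts

# ----------------------------------------------------------------------
# Per-locus primitives
# ----------------------------------------------------------------------


def gene_diversity(freq: float, n_alleles: int) -> float:
    """Unbiased expected heterozygosity (n/(n-1)) * (1 - p^2 - q^2)."""
    if n_alleles < 2:
        return float("nan")
    p = freq
    return (n_alleles / (n_alleles - 1.0)) * (1.0 - p * p - (1 - p) * (1 - p))


def nei_distance(freq_x: float, freq_y: float, *, cap: float = 10.0) -> float:
    """Nei's standard distance for one biallelic locus.

    -ln(J_XY / sqrt(J_X J_Y)) with J_X = p^2+q^2 etc.; 0 for identical
    frequencies, capped at ``cap`` when the alleles are disjoint
    (J_XY = 0, infinite distance).
    """
    if freq_x == freq_y:
        return 0.0
    jx = freq_x**2 + (1 - freq_x) ** 2
    jy = freq_y**2 + (1 - freq_y) ** 2
    jxy = freq_x * freq_y + (1 - freq_x) * (1 - freq_y)
    if jxy <= 0.0:
        return cap
    return min(float(-np.log(jxy / np.sqrt(jx * jy))), cap)


def admixture_estimate(freq_adm: float, freq_p1: float, freq_p2: float,
                       *, tol: float = 1e-12) -> float:
    """Per-locus admixture proportion (p_adm - p2) / (p1 - p2).

    NaN (undefined) when the parental frequencies differ by less than
    ``tol``.
    """
    if abs(freq_p1 - freq_p2) < tol:
        return float("nan")
    return float((freq_adm - freq_p2) / (freq_p1 - freq_p2))


# ----------------------------------------------------------------------
# Summary-statistic layout and vector
# ----------------------------------------------------------------------


@dataclass
class StatLayout:
    """Declared composition of the summary-statistic vector.

    ``groups`` get the two one-sample statistics, ``pairs`` the two
    two-sample statistics, and ``trios`` (admixed, parent1, parent2)
    the four admixture statistics, concatenated in declaration order.
    """

    groups: list[str]
    pairs: list[tuple[str, str]] = field(default_factory=list)
    trios: list[tuple[str, str, str]] = field(default_factory=list)
    nei_cap: float = 10.0
    adm_tol: float = 1e-12

    @classmethod
    def default_for(cls, groups: list[str],
                    trios: list[tuple[str, str, str]] | None = None
                    ) -> "StatLayout":
        """All groups, all unordered pairs, and the given trios."""
        pairs = [
            (groups[i], groups[j])
            for i in range(len(groups))
            for j in range(i + 1, len(groups))
        ]
        return cls(groups=list(groups), pairs=pairs, trios=trios or [])

    def names(self) -> list[str]:
        out = []
        for g in self.groups:
            out += [f"prop_null_gd({g})", f"mean_gd_poly({g})"]
        for a, b in self.pairs:
            out += [f"prop_null_nei({a},{b})", f"var_nei({a},{b})"]
        for a, p1, p2 in self.trios:
            base = f"({a}|{p1},{p2})"
            out += [
                f"prop_null_adm{base}", f"mean_adm_nonnull{base}",
                f"var_adm_nonnull{base}", f"mean_adm_all{base}",
            ]
        return out

    @property
    def size(self) -> int:
        return 2 * len(self.groups) + 2 * len(self.pairs) + 4 * len(self.trios)


def _safe_mean(x: np.ndarray) -> float:
    return float(x.mean()) if x.size else 0.0


def _safe_var(x: np.ndarray) -> float:
    return float(x.var(ddof=1)) if x.size > 1 else 0.0


def stats_from_counts(derived: np.ndarray, n_alleles: np.ndarray,
                      groups: list[str], layout: StatLayout) -> np.ndarray:
    """Summary-statistic vector from per-group allele counts.

    ``derived``/``n_alleles`` are (n_loci, n_groups) arrays of derived
    (alt) allele counts and called-allele totals; ``groups`` names the
    columns.  Loci where an ingredient group has fewer than two called
    alleles are excluded from the statistics that need it.
    """
    derived = np.asarray(derived, dtype=float)
    n_alleles = np.asarray(n_alleles, dtype=float)
    gi = {g: k for k, g in enumerate(groups)}
    for g in layout.groups:
        if g not in gi:
            raise ValueError(f"layout group {g!r} absent from counts")
        if not (n_alleles[:, gi[g]] >= 2).any():
            raise ValueError(f"group {g!r} has no loci with >=2 alleles")
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, derived / np.where(n_alleles > 0,
                                                          n_alleles, 1),
                        np.nan)
    vec: list[float] = []

    for g in layout.groups:
        k = gi[g]
        ok = n_alleles[:, k] >= 2
        n = n_alleles[ok, k]
        p = freq[ok, k]
        gd = (n / (n - 1.0)) * (1.0 - p**2 - (1 - p) ** 2)
        null = gd == 0.0
        vec.append(_safe_mean(null.astype(float)))
        vec.append(_safe_mean(gd[~null]))

    for a, b in layout.pairs:
        ka, kb = gi[a], gi[b]
        ok = (n_alleles[:, ka] >= 2) & (n_alleles[:, kb] >= 2)
        px, py = freq[ok, ka], freq[ok, kb]
        jx = px**2 + (1 - px) ** 2
        jy = py**2 + (1 - py) ** 2
        jxy = px * py + (1 - px) * (1 - py)
        with np.errstate(divide="ignore"):
            d = np.where(
                jxy > 0, -np.log(
                    np.where(jxy > 0, jxy, 1) / np.sqrt(jx * jy)
                ), np.inf,
            )
        d = np.where(px == py, 0.0, np.minimum(d, layout.nei_cap))
        null = d == 0.0
        vec.append(_safe_mean(null.astype(float)))
        vec.append(_safe_var(d[~null]))

    for a, p1, p2 in layout.trios:
        ka, k1, k2 = gi[a], gi[p1], gi[p2]
        ok = (
            (n_alleles[:, ka] >= 2)
            & (n_alleles[:, k1] >= 2)
            & (n_alleles[:, k2] >= 2)
        )
        pa, q1, q2 = freq[ok, ka], freq[ok, k1], freq[ok, k2]
        defined = np.abs(q1 - q2) >= layout.adm_tol
        est = np.where(
            defined, (pa - q2) / np.where(defined, q1 - q2, 1), np.nan
        )
        est = est[defined]
        null = est == 0.0
        vec.append(_safe_mean(null.astype(float)))
        vec.append(_safe_mean(est[~null]))
        vec.append(_safe_var(est[~null]))
        vec.append(_safe_mean(est))

    return np.asarray(vec)


def summarize(gm, pm, layout: StatLayout) -> np.ndarray:
    """Summary-statistic vector of an observed genotype matrix."""
    from .simulate import counts_from_matrix

    pm.check_covers(gm)
    groups = list(
        dict.fromkeys(layout.groups
                      + [g for p in layout.pairs for g in p]
                      + [g for t in layout.trios for g in t])
    )
    for g in groups:
        if g not in pm.groups:
            raise ValueError(f"group {g!r} absent from population map")
        if not pm.individuals_in(group=g):
            raise ValueError(f"group {g!r} is empty")
    counts, n_all = counts_from_matrix(gm, pm, groups)
    return stats_from_counts(counts, n_all, groups, layout)


# ----------------------------------------------------------------------
# Reference table
# ----------------------------------------------------------------------


@dataclass
class ReferenceTable:
    """Simulated (scenario, parameters, statistics) records.

    ``sd`` holds the per-statistic standardization constants (standard
    deviation across the table; constant statistics get 1 so they
    contribute nothing to distances).
    """

    params: pd.DataFrame          # includes a "scenario" column
    stats: np.ndarray             # (N, S)
    stat_names: list[str]
    layout: StatLayout | None = None
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.params) != len(self.stats):
            raise ValueError("params/stats length mismatch")
        if self.stats.shape[1] != len(self.stat_names):
            raise ValueError("stat_names/stats width mismatch")
        if self.sd is None:
            if len(self.stats) == 0:
                self.sd = np.ones(self.stats.shape[1])
            else:
                sd = self.stats.std(axis=0, ddof=0)
                sd[sd == 0] = 1.0
                self.sd = sd

    def __len__(self) -> int:
        return len(self.params)

    @property
    def scenarios(self) -> list[str]:
        return list(dict.fromkeys(self.params["scenario"]))

    def standardized(self, vectors: np.ndarray | None = None) -> np.ndarray:
        v = self.stats if vectors is None else np.atleast_2d(vectors)
        return v / self.sd

    def save(self, path) -> None:
        """Persist as TSV with a JSON header line ('#'-prefixed):
        layout, statistic names and standardization constants."""
        import json

        header = {
            "stat_names": self.stat_names,
            "sd": list(map(float, self.sd)),
        }
        if self.layout is not None:
            header["layout"] = {
                "groups": self.layout.groups,
                "pairs": [list(p) for p in self.layout.pairs],
                "trios": [list(t) for t in self.layout.trios],
                "nei_cap": self.layout.nei_cap,
                "adm_tol": self.layout.adm_tol,
            }
        frame = pd.concat(
            [self.params.reset_index(drop=True),
             pd.DataFrame(self.stats, columns=self.stat_names)],
            axis=1,
        )
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header, sort_keys=True) + "\n")
            frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "ReferenceTable":
        import json

        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#"):
                raise ValueError("missing JSON header line")
            header = json.loads(first[1:])
            frame = pd.read_csv(fh, sep="\t")
        stat_names = header["stat_names"]
        layout = None
        if "layout" in header:
            ld = header["layout"]
            layout = StatLayout(
                groups=ld["groups"],
                pairs=[tuple(p) for p in ld["pairs"]],
                trios=[tuple(t) for t in ld["trios"]],
                nei_cap=ld["nei_cap"], adm_tol=ld["adm_tol"],
            )
        return cls(
            params=frame[[c for c in frame.columns
                          if c not in stat_names]],
            stats=frame[stat_names].to_numpy(dtype=float),
            stat_names=stat_names,
            layout=layout,
            sd=np.asarray(header["sd"], dtype=float),
        )

    def for_scenario(self, name: str) -> "ReferenceTable":
        """Sub-table of one scenario, keeping the full-table sd."""
        sel = (self.params["scenario"] == name).to_numpy()
        if not sel.any():
            raise ValueError(f"scenario {name!r} not in table")
        return ReferenceTable(
            params=self.params.loc[sel].reset_index(drop=True),
            stats=self.stats[sel],
            stat_names=self.stat_names,
            layout=self.layout,
            sd=self.sd,
        )


def build_reference_table(
    scenarios: dict[str, DemographicScenario],
    priors: PriorSet | dict[str, PriorSet],
    n_per_scenario: int,
    n_loci: int,
    sample_sizes: dict[str, int],
    layout: StatLayout,
    seed: int,
) -> ReferenceTable:
    """Draw, simulate, and summarize; deterministic given ``seed``."""
    if not scenarios:
        raise ValueError("at least one scenario required")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    stats: list[np.ndarray] = []
    for name, sc in scenarios.items():
        ps = priors[name] if isinstance(priors, dict) else priors
        for _ in range(n_per_scenario):
            draw = ps.sample(rng)
            kseed = int(rng.integers(0, 2**31 - 1))
            counts, n_hap, _ = simulate_counts(
                sc, draw, n_loci, sample_sizes, kseed
            )
            n_all = np.broadcast_to(n_hap, counts.shape)
            stats.append(
                stats_from_counts(counts, n_all, sc.populations, layout)
            )
            rows.append({"scenario": name, **draw})
    return ReferenceTable(
        params=pd.DataFrame(rows),
        stats=np.vstack(stats),
        stat_names=layout.names(),
        layout=layout,
    )


# ----------------------------------------------------------------------
# Rejection
# ----------------------------------------------------------------------


@dataclass
class Accepted:
    """Closest records to an observed vector, with distances."""

    table: ReferenceTable
    indices: np.ndarray
    distances: np.ndarray
    observed: np.ndarray

    @property
    def params(self) -> pd.DataFrame:
        return self.table.params.iloc[self.indices].reset_index(drop=True)

    @property
    def stats(self) -> np.ndarray:
        return self.table.stats[self.indices]


def reject(rt: ReferenceTable, observed: np.ndarray,
           tolerance: float) -> Accepted:
    """Keep the ceil(tolerance * N) records closest to ``observed``
    (Euclidean distance on standardized vectors)."""
    if len(rt) == 0:
        raise ValueError("empty reference table")
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    obs = np.asarray(observed, dtype=float)
    if obs.shape != (len(rt.stat_names),):
        raise ValueError("observed vector has wrong layout")
    z = rt.standardized()
    zo = obs / rt.sd
    d = np.sqrt(((z - zo) ** 2).sum(axis=1))
    n_keep = int(np.ceil(tolerance * len(rt)))
    order = np.argsort(d, kind="stable")[:n_keep]
    return Accepted(table=rt, indices=order, distances=d[order],
                    observed=obs)


# ----------------------------------------------------------------------
# Regression adjustment
# ----------------------------------------------------------------------


def _logit_transform(x, lo, hi, eps=1e-9):
    span = hi - lo
    u = np.clip((x - lo) / span, eps, 1 - eps)
    return np.log(u / (1 - u))


def _logit_back(z, lo, hi):
    return lo + (hi - lo) / (1.0 + np.exp(-z))


def _weighted_quantile(x, w, q):
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(q, cw, x)


@dataclass
class PosteriorSample:
    """Accepted draws with regression-adjusted values and weights."""

    raw: pd.DataFrame
    adjusted: pd.DataFrame
    weights: np.ndarray
    point_estimates: pd.DataFrame  # per-parameter mean/median/mode/CI
    adjusted_ok: bool = True

    def parameter_names(self) -> list[str]:
        return list(self.adjusted.columns)


def _point_estimates(values: pd.DataFrame, w: np.ndarray) -> pd.DataFrame:
    from scipy.stats import gaussian_kde

    rows = []
    wn = w / w.sum()
    for name in values.columns:
        x = values[name].to_numpy(dtype=float)
        mean = float(np.sum(wn * x))
        median, lo, hi = _weighted_quantile(
            x, wn, np.array([0.5, 0.025, 0.975])
        )
        if np.ptp(x) > 0:
            try:
                kde = gaussian_kde(x, weights=wn)
                grid = np.linspace(x.min(), x.max(), 512)
                mode = float(grid[np.argmax(kde(grid))])
            except np.linalg.LinAlgError:
                mode = float(median)
        else:
            mode = float(x[0])
        rows.append(
            {"parameter": name, "mean": mean, "median": float(median),
             "mode": mode, "ci_2.5%": float(lo), "ci_97.5%": float(hi)}
        )
    return pd.DataFrame(rows).set_index("parameter")


def regression_adjust(accepted: Accepted,
                      bounds: dict[str, tuple[float, float]],
                      parameters: list[str] | None = None
                      ) -> PosteriorSample:
    """Weighted local linear regression adjustment of accepted draws.

    Epanechnikov weights on distance (bandwidth = the largest accepted
    distance); each parameter is mapped to an unbounded scale (logit on
    its prior bounds; identity for unbounded priors), regressed on the
    standardized statistics, and corrected to the observed vector.  A
    singular design falls back to the unadjusted rejection sample with
    a warning.
    """
    params = accepted.params
    if parameters is None:
        parameters = [c for c in params.columns if c != "scenario"]
    n = len(params)
    S = accepted.table.standardized(accepted.stats)
    zo = accepted.observed / accepted.table.sd
    dmax = accepted.distances.max()
    if dmax == 0:
        w = np.ones(n)
    else:
        w = 1.0 - (accepted.distances / dmax) ** 2
        w = np.maximum(w, 1e-12)
    if n < S.shape[1] + 2:
        raise ValueError(
            f"need at least dim(stats)+2={S.shape[1] + 2} accepted records"
        )

    X = np.column_stack([np.ones(n), S - zo])
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    adjusted = {}
    ok = True
    for name in parameters:
        lo, hi = bounds[name]
        x = params[name].to_numpy(dtype=float)
        if np.isfinite(lo) and np.isfinite(hi):
            z = _logit_transform(x, lo, hi)
        else:
            z = x.copy()
        try:
            beta, *_ = np.linalg.lstsq(Xw, z * sw, rcond=None)
            fitted_slopes = X[:, 1:] @ beta[1:]
            z_adj = z - fitted_slopes
        except np.linalg.LinAlgError:
            warnings.warn(
                f"singular regression design for {name}; using "
                "unadjusted rejection sample", stacklevel=2,
            )
            z_adj = z
            ok = False
        if np.isfinite(lo) and np.isfinite(hi):
            adjusted[name] = _logit_back(z_adj, lo, hi)
        else:
            adjusted[name] = z_adj
    adjusted_df = pd.DataFrame(adjusted)
    return PosteriorSample(
        raw=params[parameters].reset_index(drop=True),
        adjusted=adjusted_df,
        weights=w,
        point_estimates=_point_estimates(adjusted_df, w),
        adjusted_ok=ok,
    )


# ----------------------------------------------------------------------
# Scenario choice
# ----------------------------------------------------------------------


def select_model_direct(rt: ReferenceTable, observed: np.ndarray,
                        n_closest: int = 500) -> pd.DataFrame:
    """Scenario posterior probabilities from the share of each scenario
    among the closest records, with normal-approximation binomial CIs."""
    if len(rt.scenarios) < 2:
        raise ValueError("need >= 2 scenarios for model choice")
    if n_closest > len(rt):
        raise ValueError("n_closest exceeds table size")
    acc = reject(rt, observed, n_closest / len(rt))
    labels = acc.params["scenario"].to_numpy()[: n_closest]
    rows = []
    for name in rt.scenarios:
        p = float((labels == name).mean())
        half = 1.96 * np.sqrt(max(p * (1 - p), 0.0) / n_closest)
        rows.append(
            {"scenario": name, "probability": p,
             "ci_low": max(0.0, p - half), "ci_high": min(1.0, p + half)}
        )
    return pd.DataFrame(rows).set_index("scenario")


def select_model_logistic(rt: ReferenceTable, observed: np.ndarray,
                          tolerance: float = 0.01) -> pd.DataFrame:
    """Multinomial logistic regression of scenario label on standardized
    statistics over the accepted set, evaluated at the observed vector.

    CIs come from the delta method on the fitted coefficient
    covariance; on perfect separation or non-convergence the fit falls
    back to a ridge-regularized estimate with binomial-style CIs and a
    warning.
    """
    names = rt.scenarios
    if len(names) < 2:
        raise ValueError("need >= 2 scenarios for model choice")
    acc = reject(rt, observed, tolerance)
    S = rt.standardized(acc.stats)
    zo = (acc.observed / rt.sd)[None, :]
    y = pd.Categorical(acc.params["scenario"], categories=names).codes

    import statsmodels.api as sm

    X = sm.add_constant(S - zo, has_constant="add")
    x0 = np.zeros(X.shape[1])
    x0[0] = 1.0  # observed point: constant term only
    present = sorted(set(y))
    probs = {}
    ci = {}
    if len(present) == 1:
        # every accepted record comes from one scenario: degenerate,
        # perfectly separated case
        rows = []
        for code, name in enumerate(names):
            p = 1.0 if code == present[0] else 0.0
            rows.append({"scenario": name, "probability": p,
                         "ci_low": p, "ci_high": p})
        return pd.DataFrame(rows).set_index("scenario")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MNLogit(y, X)
            fit = model.fit(disp=False, maxiter=200)
        if not np.all(np.isfinite(fit.params.to_numpy() if hasattr(
                fit.params, "to_numpy") else fit.params)):
            raise np.linalg.LinAlgError("non-finite coefficients")
        beta = np.asarray(fit.params)          # (k_exog, J-1)
        eta = np.concatenate([[0.0], x0 @ beta])
        eta -= eta.max()
        e = np.exp(eta)
        p = e / e.sum()
        # delta method for each category probability
        cov = np.asarray(fit.cov_params())
        J = len(present)
        k = X.shape[1]
        grads = np.zeros((J, (J - 1) * k))
        for j in range(J):
            for m in range(1, J):
                dp = p[j] * ((1.0 if m == j else 0.0) - p[m])
                grads[j, (m - 1) * k:m * k] = dp * x0
        var = np.einsum("ji,ik,jk->j", grads, cov, grads)
        var = np.maximum(var, 0.0)
        half = 1.96 * np.sqrt(var)
        for idx, code in enumerate(present):
            probs[names[code]] = float(p[idx])
            ci[names[code]] = (
                float(max(0.0, p[idx] - half[idx])),
                float(min(1.0, p[idx] + half[idx])),
            )
    except Exception as exc:  # separation / singular Hessian / no converge
        warnings.warn(
            f"multinomial logit failed ({exc}); using regularized fit",
            stacklevel=2,
        )
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1.0, max_iter=1000)
        clf.fit(S - zo, y)
        p_hat = clf.predict_proba(np.zeros((1, S.shape[1])))[0]
        n = len(y)
        for idx, code in enumerate(clf.classes_):
            pj = float(p_hat[idx])
            half = 1.96 * np.sqrt(max(pj * (1 - pj), 0.0) / n)
            probs[names[code]] = pj
            ci[names[code]] = (max(0.0, pj - half), min(1.0, pj + half))

    rows = []
    for name in names:
        p = probs.get(name, 0.0)
        lo, hi = ci.get(name, (0.0, 0.0))
        rows.append({"scenario": name, "probability": p,
                     "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows).set_index("scenario")


# ----------------------------------------------------------------------
# Accuracy metrics and scaling
# ----------------------------------------------------------------------


@dataclass
class AccuracyReport:
    """Relative error metrics per parameter, from pseudo-observed test
    datasets with known truth.

    RRMISE: sqrt of the mean (over test sets and posterior draws) of
    squared relative errors.  RMeanAD: mean absolute relative
    deviation.  RRMSE: sqrt of the mean squared relative error of the
    posterior-mean point estimate.
    """

    table: pd.DataFrame  # parameter x (rrmise, rmeanad, rrmse)
    n_test: int
    n_excluded: int = 0


def _relative_metrics(truths: list[dict[str, float]],
                      posteriors: list[PosteriorSample],
                      parameters: list[str]) -> pd.DataFrame:
    rows = []
    for name in parameters:
        sq_int, abs_dev, sq_point = [], [], []
        for truth, post in zip(truths, posteriors):
            theta = truth[name]
            if theta == 0:
                continue
            draws = post.adjusted[name].to_numpy(dtype=float)
            wn = post.weights / post.weights.sum()
            rel = (draws - theta) / theta
            sq_int.append(float(np.sum(wn * rel**2)))
            abs_dev.append(float(np.sum(wn * np.abs(rel))))
            point = float(np.sum(wn * draws))
            sq_point.append(((point - theta) / theta) ** 2)
        rows.append({
            "parameter": name,
            "rrmise": float(np.sqrt(np.mean(sq_int))) if sq_int else np.nan,
            "rmeanad": float(np.mean(abs_dev)) if abs_dev else np.nan,
            "rrmse": float(np.sqrt(np.mean(sq_point))) if sq_point else np.nan,
        })
    return pd.DataFrame(rows).set_index("parameter")


def accuracy_metrics(rt: ReferenceTable, scenario: DemographicScenario,
                     priors: PriorSet, n_loci: int,
                     sample_sizes: dict[str, int], seed: int,
                     *, n_test: int = 100, tolerance: float = 0.01,
                     posterior: PosteriorSample | None = None
                     ) -> dict[str, AccuracyReport]:
    """Estimation-accuracy metrics from pseudo-observed datasets.

    Test parameters are drawn from the prior (always) and, when a
    ``posterior`` sample is supplied, from its adjusted draws too; each
    pseudo-observed dataset is pushed through rejection + regression
    against ``rt`` restricted to ``scenario``.  Returns reports keyed
    ``"prior"`` (and ``"posterior"``).
    """
    if n_test < 1:
        raise ValueError("n_test must be >= 1")
    rng = np.random.default_rng(seed)
    sub = rt.for_scenario(scenario.name)
    layout = rt.layout
    parameters = [c for c in sub.params.columns if c != "scenario"]
    bounds = priors.bounds()

    def run_tests(draws: list[dict[str, float]]):
        truths, posts = [], []
        n_excluded = 0
        for truth in draws:
            kseed = int(rng.integers(0, 2**31 - 1))
            counts, n_hap, _ = simulate_counts(
                scenario, truth, n_loci, sample_sizes, kseed
            )
            n_all = np.broadcast_to(n_hap, counts.shape)
            obs = stats_from_counts(
                counts, n_all, scenario.populations, layout
            )
            acc = reject(sub, obs, tolerance)
            try:
                post = regression_adjust(acc, bounds, parameters)
            except ValueError:
                n_excluded += 1
                continue
            truths.append(truth)
            posts.append(post)
        return truths, posts, n_excluded

    reports: dict[str, AccuracyReport] = {}
    prior_draws = priors.sample_many(n_test, rng)
    truths, posts, nex = run_tests(prior_draws)
    reports["prior"] = AccuracyReport(
        table=_relative_metrics(truths, posts, parameters),
        n_test=n_test, n_excluded=nex,
    )
    if posterior is not None:
        wn = posterior.weights / posterior.weights.sum()
        idx = rng.choice(len(posterior.adjusted), size=n_test, p=wn)
        post_draws = [
            {k: float(posterior.adjusted[k].iloc[i]) for k in parameters}
            for i in idx
        ]
        # posterior draws may violate hard constraints slightly after
        # adjustment; drop violators
        post_draws = [d for d in post_draws if priors.satisfied(d)]
        truths, posts, nex = run_tests(post_draws)
        reports["posterior"] = AccuracyReport(
            table=_relative_metrics(truths, posts, parameters),
            n_test=len(post_draws), n_excluded=nex,
        )
    return reports


def scale_parameters(sample: PosteriorSample, mean_ne: float,
                     direction: str = "to_scaled") -> PosteriorSample:
    """Convert between natural units and mean-Ne-scaled units.

    ``to_scaled`` divides every parameter by ``mean_ne``; ``to_natural``
    multiplies.  Round-trip is the identity.
    """
    if mean_ne <= 0:
        raise ValueError("mean_ne must be positive")
    if direction not in ("to_scaled", "to_natural"):
        raise ValueError("direction must be 'to_scaled' or 'to_natural'")
    f = 1.0 / mean_ne if direction == "to_scaled" else mean_ne
    pe = sample.point_estimates.copy()
    pe[["mean", "median", "mode", "ci_2.5%", "ci_97.5%"]] *= f
    return PosteriorSample(
        raw=sample.raw * f,
        adjusted=sample.adjusted * f,
        weights=sample.weights.copy(),
        point_estimates=pe,
        adjusted_ok=sample.adjusted_ok,
    )
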