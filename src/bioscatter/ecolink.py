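"""Linking radar bioscatterer communities to light-trap moth communities.

The ground-truthing side of the analysis: species-level morphometric
traits are extended with derived quantities (fresh mass, thorax depth,
aspect ratios) and reduced with a PCA; nightly community statistics
(community-weighted mean trait scores, summed abundance, biomass and
mass-squared abundance) constrain a canonical correspondence analysis
(CCA) of the nightly cluster composition; Shannon diversity, functional
dispersion (FDis) and a Pearson/Spearman correlation battery complete
the comparison.

All ordination machinery is implemented on the chi-square residual
formulation: with community matrix ``Y`` (nights x clusters), grand
total ``y..``, ``P = Y / y..``, row and column sums ``r`` and ``c``,
the residual matrix is ``Q = D_r^{-1/2} (P - r c^T) D_c^{-1/2}``.
Total inertia is ``||Q||_F^2``; CCA projects ``Q`` onto the row-weighted
span of the standardized constraints before the SVD, so constrained and
unconstrained inertia sum to the total exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import svd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, shapiro, spearmanr

MEASURED_TRAITS = (
    "forewing_length",
    "body_length",
    "thorax_length",
    "abdomen_length",
    "thorax_width",
    "abdomen_width",
)
DERIVED_TRAITS = ("mass", "thorax_depth", "lateral_aspect", "anterior_aspect")
ALL_TRAITS = MEASURED_TRAITS + DERIVED_TRAITS


@dataclass(frozen=True)
class MassModel:
    """Allometric fresh-mass model: mass_mg = a * (body_length_mm) ** b.

    The default coefficients give a plausible macro-moth fresh mass
    (about 70 mg at 20 mm body length); they are package defaults, not
    literature-asserted constants, and should be overridden when a
    calibrated allometry is available.
    """

    a: float = 0.04
    b: float = 2.5


def derive_traits(
    measured: pd.DataFrame,
    mass_model: MassModel = MassModel(),
    thorax_depth: pd.Series | None = None,
) -> pd.DataFrame:
    """Extend the six measured traits with the four derived ones.

    Thorax depth comes from, in order of precedence: the explicit
    ``thorax_depth`` argument, a ``thorax_depth`` column of ``measured``,
    or the circular-cross-section default (depth = thorax width).  The
    aspect ratios are lateral = body_length / thorax_depth and
    anterior = thorax_width / thorax_depth.
    """
    missing = [t for t in MEASURED_TRAITS if t not in measured.columns]
    if missing:
        raise ValueError(f"measured trait(s) missing: {missing}")
    df = measured[list(MEASURED_TRAITS)].astype(float).copy()
    if (df <= 0).any().any():
        bad = df.index[(df <= 0).any(axis=1)].tolist()
        raise ValueError(f"non-positive measurement(s) for species: {bad}")
    if thorax_depth is not None:
        depth = thorax_depth.reindex(df.index).astype(float)
    elif "thorax_depth" in measured.columns:
        depth = measured["thorax_depth"].astype(float)
    else:
        depth = df["thorax_width"]
    if (depth <= 0).any():
        raise ValueError("thorax depth must be positive")
    df["mass"] = mass_model.a * df["body_length"] ** mass_model.b
    df["thorax_depth"] = depth
    df["lateral_aspect"] = df["body_length"] / depth
    df["anterior_aspect"] = df["thorax_width"] / depth
    return df


@dataclass
class TraitPCA:
    loadings: np.ndarray  # (n_traits, n_components) correlation eigenvectors
    scores: pd.DataFrame  # species x PC scores
    variance_fraction: np.ndarray
    trait_names: tuple


def trait_pca(traits: pd.DataFrame, n_components: int = 2) -> TraitPCA:
    """PCA of z-standardized traits via the correlation-matrix eigenproblem.

    Component signs are fixed so each retained component's loading sum
    is non-negative; species scores are centred by construction.
    """
    X = traits.astype(float).to_numpy()
    n, p = X.shape
    if n < 3:
        raise ValueError("at least 3 species required")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        flat = [traits.columns[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant trait column(s): {flat}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0, None)
    k = min(n_components, p)
    load = eigvec[:, :k].copy()
    signs = np.where(load.sum(axis=0) < 0, -1.0, 1.0)
    load *= signs
    scores = Z @ load
    return TraitPCA(
        loadings=load,
        scores=pd.DataFrame(
            scores, index=traits.index, columns=[f"PC{i+1}" for i in range(k)]
        ),
        variance_fraction=eigval[:k] / eigval.sum(),
        trait_names=tuple(traits.columns),
    )


def cwm(scores, weights) -> float:
    """Community-weighted mean: sum(w * x) / sum(w)."""
    x = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    tot = w.sum()
    if tot == 0:
        raise ValueError("all-zero weights")
    return float((w * x).sum() / tot)


@dataclass
class CommunityStats:
    """Per-night community statistics table.

    Columns: cwm_pc1_abund, cwm_pc2_abund, cwm_pc1_biomass,
    cwm_pc2_biomass, abundance, biomass, msa.  Nights with zero catch
    have NaN CWMs (they are dropped from ordination).
    """

    table: pd.DataFrame


def community_stats(
    catches: pd.DataFrame, traits: pd.DataFrame, pca: TraitPCA
) -> CommunityStats:
    """Nightly sums and community-weighted means.

    ``catches`` is nights x species (non-negative counts); ``traits``
    must carry a ``mass`` column; ``pca`` supplies per-species PC1/PC2
    scores.  Biomass = sum(mass * n); MSA = sum(mass^2 * n).
    """
    missing = [s for s in catches.columns if s not in traits.index]
    if missing:
        raise ValueError(f"species missing from trait table: {missing}")
    species = list(catches.columns)
    mass = traits.loc[species, "mass"].to_numpy(dtype=float)
    pc1 = pca.scores.loc[species, "PC1"].to_numpy()
    pc2 = pca.scores.loc[species, "PC2"].to_numpy()
    rows = {}
    for night, counts in catches.iterrows():
        n = counts.to_numpy(dtype=float)
        if np.any(n < 0):
            raise ValueError(f"negative abundance on night {night!r}")
        abundance = n.sum()
        biomass = float((mass * n).sum())
        msa = float((mass**2 * n).sum())
        if abundance == 0:
            warnings.warn(f"night {night!r} has zero catch; CWMs undefined")
            cw = dict.fromkeys(
                ("cwm_pc1_abund", "cwm_pc2_abund", "cwm_pc1_biomass",
                 "cwm_pc2_biomass"), np.nan,
            )
        else:
            bw = mass * n
            cw = {
                "cwm_pc1_abund": cwm(pc1, n),
                "cwm_pc2_abund": cwm(pc2, n),
                "cwm_pc1_biomass": cwm(pc1, bw),
                "cwm_pc2_biomass": cwm(pc2, bw),
            }
        rows[night] = {
            **cw, "abundance": float(abundance), "biomass": biomass, "msa": msa
        }
    return CommunityStats(table=pd.DataFrame.from_dict(rows, orient="index"))


# -- canonical correspondence analysis ------------------------------------

@dataclass
class CCAResult:
    eigenvalues: np.ndarray  # constrained axes
    unconstrained_eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    proportion_constrained: float
    axis_proportions: np.ndarray  # per constrained axis, of constrained inertia
    site_scores: np.ndarray
    species_scores: np.ndarray
    biplot_scores: np.ndarray
    q_rank: int  # constrained degrees of freedom
    n_sites: int
    constraint_names: tuple = ()
    permutation: dict = field(default_factory=dict)


def _chi_square_residuals(Y: np.ndarray):
    total = Y.sum()
    if total <= 0:
        raise ValueError("community matrix has no counts")
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if np.any(r <= 0) or np.any(c <= 0):
        raise ValueError("community matrix has empty rows or columns")
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return Q, r, c


def _weighted_standardize(X: np.ndarray, r: np.ndarray):
    """Row-weight-centred, row-weight-scaled constraint matrix.

    Columns that are constant across sites centre to zero (the
    intercept is implicit in the chi-square centring) and are dropped;
    the surviving column indices are returned alongside.
    """
    mean = r @ X
    Xc = X - mean
    var = r @ (Xc**2)
    keep = var > 0
    Xs = Xc[:, keep] / np.sqrt(var[keep])
    return Xs, np.flatnonzero(keep)


def cca_fit(community, constraints, constraint_names=None) -> CCAResult:
    """Classical CCA of a nights x clusters matrix on explanatory columns.

    Constrained eigenvalues come from the SVD of the chi-square residual
    matrix projected onto the row-weighted span of the standardized
    constraints; unconstrained eigenvalues from the residual complement.
    The two sets sum to the total inertia (to 1e-8 relative).
    """
    Y = np.asarray(community, dtype=float)
    X = np.asarray(constraints, dtype=float)
    if np.any(Y < 0):
        raise ValueError("community matrix must be non-negative")
    if Y.shape[0] != X.shape[0]:
        raise ValueError("community and constraints disagree on night count")
    Q, r, c = _chi_square_residuals(Y)
    total_inertia = float((Q**2).sum())

    Xs, kept = _weighted_standardize(X, r)
    if Xs.shape[1] == 0:
        # all constraints are null after chi-square centring
        u_res, s_res, _ = svd(Q, full_matrices=False)
        eig_res = (s_res**2)
        return CCAResult(
            eigenvalues=np.empty(0),
            unconstrained_eigenvalues=eig_res[eig_res > 1e-12],
            total_inertia=total_inertia,
            constrained_inertia=0.0,
            proportion_constrained=0.0,
            axis_proportions=np.empty(0),
            site_scores=np.empty((Y.shape[0], 0)),
            species_scores=np.empty((Y.shape[1], 0)),
            biplot_scores=np.empty((X.shape[1], 0)),
            q_rank=0,
            n_sites=Y.shape[0],
            constraint_names=tuple(constraint_names or ()),
        )
    Z = Xs * np.sqrt(r)[:, None]  # row-weighted design
    # orthonormal basis of the weighted constraint span
    u_basis, s_basis, _ = svd(Z, full_matrices=False)
    rank = int((s_basis > s_basis.max() * 1e-10).sum()) if s_basis.size else 0
    if rank < Z.shape[1]:
        raise ValueError("constraint matrix is rank-deficient")
    B = u_basis[:, :rank]
    Q_fit = B @ (B.T @ Q)
    Q_res = Q - Q_fit

    u, s, vt = svd(Q_fit, full_matrices=False)
    n_axes = min(rank, min(Y.shape) - 1)
    eig = (s**2)[:n_axes]
    u_res, s_res, _ = svd(Q_res, full_matrices=False)
    eig_res = (s_res**2)
    eig_res = eig_res[eig_res > 1e-12]

    constrained = float(eig.sum())
    site = (u[:, :n_axes] * s[:n_axes]) / np.sqrt(r)[:, None]
    species = vt[:n_axes].T / np.sqrt(c)[:, None]
    # biplot scores: weighted correlations of constraints with site axes
    with np.errstate(invalid="ignore", divide="ignore"):
        lc = u[:, :n_axes]
        biplot = Xs.T @ (np.sqrt(r)[:, None] * (lc / np.maximum(s[:n_axes], 1e-300)))
        norms = np.linalg.norm(biplot, axis=0, keepdims=True)
        biplot = biplot / np.maximum(norms, 1e-300) * np.sqrt(
            np.maximum(eig / max(constrained, 1e-300), 0)
        )
    return CCAResult(
        eigenvalues=eig,
        unconstrained_eigenvalues=eig_res,
        total_inertia=total_inertia,
        constrained_inertia=constrained,
        proportion_constrained=constrained / total_inertia if total_inertia else 0.0,
        axis_proportions=eig / constrained if constrained > 0 else eig * 0.0,
        site_scores=site,
        species_scores=species,
        biplot_scores=biplot,
        q_rank=rank,
        n_sites=Y.shape[0],
        constraint_names=tuple(constraint_names or ()),
    )


def _pseudo_f(constrained, residual, q, n):
    df_res = n - q - 1
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    return (constrained / q) / (residual / df_res), (q, df_res)


def cca_permutation(
    community,
    constraints,
    n_perm: int = 999,
    seed: int = 0,
    mode: str = "overall",
    constraint_names=None,
) -> dict:
    """Permutation tests for a fitted CCA.

    ``overall`` permutes whole rows of the constraint matrix and tests
    the global pseudo-F; ``axes`` tests each constrained axis; ``sequential``
    adds terms in column order, permuting the residuals of the previously
    entered terms; ``margin`` tests each term given all others.
    p = (1 + #{F* >= F}) / (1 + n_perm), seed-reproducible.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    Y = np.asarray(community, dtype=float)
    X = np.asarray(constraints, dtype=float)
    names = list(constraint_names or [f"x{j+1}" for j in range(X.shape[1])])
    rng = np.random.default_rng(seed)
    n = Y.shape[0]
    base = cca_fit(Y, X)
    resid_inertia = base.total_inertia - base.constrained_inertia
    out = {"mode": mode, "n_perm": n_perm}

    if mode == "overall":
        f_obs, df = _pseudo_f(base.constrained_inertia, resid_inertia, base.q_rank, n)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            res = cca_fit(Y, X[perm])
            f_p, _ = _pseudo_f(
                res.constrained_inertia,
                res.total_inertia - res.constrained_inertia,
                res.q_rank,
                n,
            )
            count += f_p >= f_obs
        out.update(f=f_obs, df=df, p=(1 + count) / (1 + n_perm))
        return out

    if mode == "axes":
        df_res = n - base.q_rank - 1
        results = []
        for i, lam in enumerate(base.eigenvalues):
            f_obs = lam / (resid_inertia / df_res)
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(n)
                res = cca_fit(Y, X[perm])
                lam_p = res.eigenvalues[i] if i < res.eigenvalues.size else 0.0
                f_p = lam_p / (
                    (res.total_inertia - res.constrained_inertia) / df_res
                )
                count += f_p >= f_obs
            results.append(
                {"axis": i + 1, "f": f_obs, "df": (1, df_res),
                 "p": (1 + count) / (1 + n_perm)}
            )
        out["axes"] = results
        return out

    if mode not in ("sequential", "margin"):
        raise ValueError(f"unknown mode {mode!r}")

    df_res = n - base.q_rank - 1
    results = []
    q_cols = X.shape[1]
    for j in range(q_cols):
        if mode == "sequential":
            prev = X[:, :j]
            with_term = X[:, : j + 1]
        else:  # margin: term j given all the others
            prev = np.delete(X, j, axis=1)
            with_term = X
        inertia_prev = (
            cca_fit(Y, prev).constrained_inertia if prev.shape[1] else 0.0
        )
        inertia_with = cca_fit(Y, with_term).constrained_inertia
        term_inertia = inertia_with - inertia_prev
        f_obs = term_inertia / (resid_inertia / df_res)
        term = X[:, j]
        if prev.shape[1]:
            # permute residuals of the term after removing the fitted part
            coef, *_ = np.linalg.lstsq(
                np.column_stack([np.ones(n), prev]), term, rcond=None
            )
            fitted = np.column_stack([np.ones(n), prev]) @ coef
            resid_term = term - fitted
        else:
            fitted = np.zeros(n)
            resid_term = term.copy()
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            term_p = fitted + resid_term[perm]
            if mode == "sequential":
                Xp = np.column_stack([prev, term_p]) if prev.shape[1] else term_p[:, None]
                inertia_p = cca_fit(Y, Xp).constrained_inertia - inertia_prev
                full_p = np.column_stack([Xp, X[:, j + 1:]])
            else:
                Xp = X.copy()
                Xp[:, j] = term_p
                inertia_p = cca_fit(Y, Xp).constrained_inertia - inertia_prev
                full_p = Xp
            res_p = cca_fit(Y, full_p)
            resid_p = res_p.total_inertia - res_p.constrained_inertia
            f_p = inertia_p / (resid_p / df_res)
            count += f_p >= f_obs
        results.append(
            {"term": names[j], "f": f_obs, "df": (1, df_res),
             "p": (1 + count) / (1 + n_perm)}
        )
    out["terms"] = results
    return out


CCA_MODEL_COLUMNS = {
    1: ("cwm_pc1_abund", "cwm_pc2_abund", "abundance", "biomass"),
    2: ("cwm_pc1_abund", "cwm_pc2_abund", "abundance", "msa"),
    3: ("cwm_pc1_biomass", "cwm_pc2_biomass", "abundance", "biomass"),
    4: ("cwm_pc1_biomass", "cwm_pc2_biomass", "abundance", "msa"),
}


def select_cca_model(stats: CommunityStats, community: pd.DataFrame):
    """Fit the four constraint variants and pick the best-fitting one.

    The four models differ in the CWM weighting (abundance vs biomass)
    and in whether summed biomass or MSA joins summed abundance as the
    mass-bearing term.  The winner maximizes the proportion of
    constrained inertia; ties break to the lowest model number.
    Returns ``(model_id, {model_id: CCAResult})``.
    """
    tab = stats.table.loc[community.index]
    keep = ~tab[list(CCA_MODEL_COLUMNS[1])].isna().any(axis=1)
    for m in (2, 3, 4):
        keep &= ~tab[list(CCA_MODEL_COLUMNS[m])].isna().any(axis=1)
    tab = tab[keep]
    Y = community.loc[tab.index]
    results = {}
    for m, cols in CCA_MODEL_COLUMNS.items():
        results[m] = cca_fit(
            Y.to_numpy(), tab[list(cols)].to_numpy(), constraint_names=cols
        )
    best = max(results, key=lambda m: (results[m].proportion_constrained, -m))
    return best, results


# -- diversity -------------------------------------------------------------

def shannon(counts) -> float:
    """Shannon diversity H = -sum(p ln p) in nats; zero classes ignored."""
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("at least one positive count required")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def fdis(traits: pd.DataFrame, abundances, correction: str = "none") -> float:
    """Functional dispersion (Laliberté & Legendre).

    Bray-Curtis dissimilarities on the raw species x trait matrix are
    embedded by principal coordinates; FDis is the abundance-weighted
    mean distance of species to the abundance-weighted centroid.
    Negative PCoA eigenvalues are dropped with a warning (the default),
    or mitigated with ``correction='sqrt'`` (element-wise square-root of
    the dissimilarities before embedding).
    """
    T = traits.astype(float).to_numpy()
    if (T < 0).any():
        raise ValueError("Bray-Curtis requires non-negative trait values")
    w = np.asarray(abundances, dtype=float)
    if w.shape[0] != T.shape[0]:
        raise ValueError("abundance vector does not match species count")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("abundances must be non-negative with a positive sum")
    present = w > 0
    T, w = T[present], w[present]
    if T.shape[0] == 1:
        return 0.0
    D = squareform(pdist(T, metric="braycurtis"))
    if correction == "sqrt":
        D = np.sqrt(D)
    coords = _pcoa(D)
    centroid = (w[:, None] * coords).sum(axis=0) / w.sum()
    dist = np.linalg.norm(coords - centroid, axis=1)
    return float((w * dist).sum() / w.sum())


def _pcoa(D: np.ndarray) -> np.ndarray:
    """Classical principal-coordinates embedding, keeping real axes."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    neg = eigval < -1e-8 * max(eigval.max(), 1.0)
    if neg.any():
        warnings.warn(
            f"{int(neg.sum())} negative PCoA eigenvalue(s) dropped; "
            "consider correction='sqrt'"
        )
    keep = eigval > 1e-8 * max(eigval.max(), 1.0)
    return eigvec[:, keep] * np.sqrt(eigval[keep])


# -- correlation battery ---------------------------------------------------

@dataclass
class CorrelationResult:
    coefficient: float
    p_value: float
    method: str  # 'pearson' | 'spearman'
    df: int
    n: int

    def __str__(self):
        sym = "R" if self.method == "pearson" else "R_s"
        return f"{sym}({self.df}) = {self.coefficient:.2f}, P = {self.p_value:.3g}"


def correlation_battery(x, y, n_min: int = 5, alpha: float = 0.05) -> CorrelationResult:
    """Pearson or Spearman correlation depending on marginal normality.

    Complete pairs only; both margins are screened with Shapiro-Wilk at
    ``alpha`` and Pearson is used only when both pass, otherwise
    Spearman with average ranks.  Two-sided p; df = n - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < n_min:
        raise ValueError(f"only {n} complete pairs; at least {n_min} required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has no defined correlation")
    normal = shapiro(x).pvalue > alpha and shapiro(y).pvalue > alpha
    if normal:
        r, p = pearsonr(x, y)
        method = "pearson"
    else:
        r, p = spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(
        coefficient=float(r), p_value=float(p), method=method, df=n - 2, n=n
    )
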