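"""Reporter classification and per-cell-type recombination-proportion tests.

Nuclei are called EGFP-only, Tomato-only, double-positive or neither from
their reporter transcript counts (threshold tau counts, default 1).  The
recombination readout per cell type is the fraction of exclusively-EGFP
nuclei among exclusive nuclei.  Whether that fraction deviates from the
grand mean is tested with an effect-coded logistic regression (sum-to-zero
cell-type contrasts, dummy-coded sample fixed effect), Wald z-tests and a
Bonferroni threshold alpha / K over the K types tested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .core_io import CountMatrix

CALLS = ("EGFP_ONLY", "TOM_ONLY", "DOUBLE", "NEITHER")


def call_reporter(cm: CountMatrix, tau: int = 1) -> pd.DataFrame:
    """Per-nucleus reporter call from eGFP / tdTomato counts.

    EGFP_ONLY iff egfp >= tau and tom < tau; TOM_ONLY symmetric; DOUBLE iff
    both >= tau; NEITHER otherwise.
    """
    rep = cm.genes["is_reporter"].to_numpy()
    if rep.sum() == 0:
        raise ValueError("no reporter features flagged in the gene table")
    ids = cm.genes.loc[rep, "gene_id"].str.lower()
    rep_idx = np.flatnonzero(rep)
    egfp_rows = rep_idx[ids.str.contains("gfp").to_numpy()]
    tom_rows = rep_idx[ids.str.contains("tom").to_numpy()]
    if egfp_rows.size == 0 or tom_rows.size == 0:
        raise ValueError("need both an eGFP and a tdTomato reporter feature")
    egfp = np.asarray(cm.counts[egfp_rows, :].sum(axis=0)).ravel()
    tom = np.asarray(cm.counts[tom_rows, :].sum(axis=0)).ravel()
    call = np.where(
        (egfp >= tau) & (tom >= tau),
        "DOUBLE",
        np.where(
            egfp >= tau, "EGFP_ONLY", np.where(tom >= tau, "TOM_ONLY", "NEITHER")
        ),
    )
    return pd.DataFrame(
        {
            "barcode": cm.nuclei["barcode"].to_numpy(),
            "sample_id": cm.nuclei["sample_id"].to_numpy(),
            "egfp_count": egfp.astype(int),
            "tom_count": tom.astype(int),
            "call": call,
        }
    )


def recombination_table(
    calls: pd.DataFrame,
    cell_types: np.ndarray | pd.Series,
    samples: np.ndarray | pd.Series | None = None,
) -> pd.DataFrame:
    """Exclusive-call counts and EGFP proportions per cell type (x sample).

    Rows with no exclusive nuclei carry NaN proportion and defined=False.
    """
    df = calls.copy()
    df["cell_type"] = np.asarray(cell_types)
    df["sample_id"] = np.asarray(samples) if samples is not None else df["sample_id"]
    df = df[df["call"].isin(["EGFP_ONLY", "TOM_ONLY"])]
    rows = []
    for ct, sub in calls.assign(cell_type=np.asarray(cell_types)).groupby("cell_type"):
        excl = sub[sub["call"].isin(["EGFP_ONLY", "TOM_ONLY"])]
        n_g = int((excl["call"] == "EGFP_ONLY").sum())
        n_t = int((excl["call"] == "TOM_ONLY").sum())
        rows.append(
            {
                "cell_type": ct,
                "n_egfp": n_g,
                "n_tom": n_t,
                "prop_egfp": n_g / (n_g + n_t) if (n_g + n_t) else np.nan,
                "defined": bool(n_g + n_t),
            }
        )
    per_type = pd.DataFrame(rows)

    per_type_sample = (
        df.groupby(["cell_type", "sample_id"])["call"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["EGFP_ONLY", "TOM_ONLY"], fill_value=0)
        .rename(columns={"EGFP_ONLY": "n_egfp", "TOM_ONLY": "n_tom"})
        .reset_index()
    )
    per_type.attrs["per_sample"] = per_type_sample
    return per_type


def proportion_glm(
    calls: pd.DataFrame,
    cell_types: np.ndarray | pd.Series,
    alpha: float = 0.05,
    include_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Effect-coded logistic regression of EGFP vs Tomato on cell type.

    Restricted to exclusive calls.  Types enter only if they have at least
    one EGFP and one Tomato nucleus in every included sample; excluded types
    are listed in ``result.attrs["excluded_types"]``.  The model is
    EGFP ~ effect-coded type + dummy-coded sample, fit by IRLS; each type's
    coefficient is its log-odds deviation from the grand mean.  The
    redundant level's deviation is recovered as minus the sum of the others
    with its SE from the coefficient covariance (algebraically identical to
    refitting with a different redundant level).  Significance is Bonferroni
    alpha / K.
    """
    df = calls.copy()
    df["cell_type"] = np.asarray(cell_types)
    if include_samples is not None:
        df = df[df["sample_id"].isin(include_samples)]
    df = df[df["call"].isin(["EGFP_ONLY", "TOM_ONLY"])].reset_index(drop=True)
    if df.empty:
        raise ValueError("no exclusive reporter calls to test")

    samples = sorted(df["sample_id"].unique())
    counts = (
        df.groupby(["cell_type", "sample_id"])["call"].value_counts().unstack(fill_value=0)
    )
    eligible = []
    excluded = []
    for ct in sorted(df["cell_type"].unique(), key=str):
        ok = True
        for s in samples:
            try:
                row = counts.loc[(ct, s)]
            except KeyError:
                ok = False
                break
            if row.get("EGFP_ONLY", 0) < 1 or row.get("TOM_ONLY", 0) < 1:
                ok = False
                break
        (eligible if ok else excluded).append(ct)
    if len(eligible) < 2:
        raise ValueError("fewer than two eligible cell types")

    sub = df[df["cell_type"].isin(eligible)].reset_index(drop=True)
    k = len(eligible)
    type_index = {ct: i for i, ct in enumerate(eligible)}
    # sum-to-zero contrasts, last type redundant
    X_type = np.zeros((len(sub), k - 1))
    for r, ct in enumerate(sub["cell_type"]):
        i = type_index[ct]
        if i < k - 1:
            X_type[r, i] = 1.0
        else:
            X_type[r, :] = -1.0
    X_cols = [f"type_{ct}" for ct in eligible[:-1]]
    X = pd.DataFrame(X_type, columns=X_cols)
    for s in samples[1:]:
        X[f"sample_{s}"] = (sub["sample_id"] == s).astype(float).to_numpy()
    X = sm.add_constant(X, prepend=True)
    y = (sub["call"] == "EGFP_ONLY").astype(float).to_numpy()

    model = sm.GLM(y, X, family=sm.families.Binomial())
    converged = True
    try:
        fit = model.fit(maxiter=200, tol=1e-10)
        mu = fit.fittedvalues
        if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10):
            converged = False  # complete separation: probabilities pinned
    except Exception:
        fit = None
        converged = False

    rows = []
    tallies = recombination_table(
        sub, sub["cell_type"].to_numpy(), sub["sample_id"].to_numpy()
    ).set_index("cell_type")
    if fit is not None:
        params = fit.params.to_numpy()
        cov = fit.cov_params().to_numpy()
        idx_types = [list(X.columns).index(c) for c in X_cols]
        for ct in eligible:
            i = type_index[ct]
            if i < k - 1:
                beta = params[idx_types[i]]
                se = float(np.sqrt(cov[idx_types[i], idx_types[i]]))
            else:
                c = np.zeros(len(params))
                for j in idx_types:
                    c[j] = -1.0
                beta = float(c @ params)
                se = float(np.sqrt(c @ cov @ c))
            if converged and se > 0:
                z = beta / se
                p = float(2 * scipy.stats.norm.sf(abs(z)))
            else:
                p = np.nan
            rows.append(
                {
                    "cell_type": ct,
                    "n_egfp": int(tallies.loc[ct, "n_egfp"]),
                    "n_tom": int(tallies.loc[ct, "n_tom"]),
                    "prop_egfp": float(tallies.loc[ct, "prop_egfp"]),
                    "beta": float(beta),
                    "se": se,
                    "wald_p": p,
                    "converged": converged,
                }
            )
    else:
        for ct in eligible:
            rows.append(
                {
                    "cell_type": ct,
                    "n_egfp": int(tallies.loc[ct, "n_egfp"]),
                    "n_tom": int(tallies.loc[ct, "n_tom"]),
                    "prop_egfp": float(tallies.loc[ct, "prop_egfp"]),
                    "beta": np.nan,
                    "se": np.nan,
                    "wald_p": np.nan,
                    "converged": False,
                }
            )
    out = pd.DataFrame(rows)
    out["bonferroni_threshold"] = alpha / k
    out["significant"] = out["wald_p"] < alpha / k
    out.attrs["excluded_types"] = excluded
    out.attrs["n_types_tested"] = k
    return out


def fs_correlation(
    recomb_fraction: np.ndarray | pd.Series, fs: np.ndarray | pd.Series
) -> tuple[float, int]:
    """Pearson correlation of per-sample recombined-CM fraction vs FS."""
    x = np.asarray(recomb_fraction, float)
    y = np.asarray(fs, float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, _ = scipy.stats.pearsonr(x, y)
    return float(r), int(x.size)
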