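"""Genotype x age linear models and positional significance mapping.

Each morphometric index is modelled as a two-way ANOVA with interaction,
``y ~ genotype + age + genotype:age``, with age categorical (the cohort
ages are discrete groups of different animals, not a longitudinal
covariate).  Main effects use Type-II sums of squares — appropriate for
mildly unbalanced cohorts (e.g. one fewer animal at the oldest age) —
and residual normality is checked with Shapiro–Wilk.  Whole-bone
profiles are fitted independently at each percent-length station with
no cross-station adjustment, preserving the station-wise inferential
scale, and p-values are banded into the four-colour significance code

    red p ≤ 0.001 < yellow p ≤ 0.01 < green p ≤ 0.05 < blue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm

__all__ = [
    "AnovaResult",
    "fit_two_way",
    "posthoc",
    "positional_analysis",
    "p_band",
    "significance_heatmap",
    "render_heatmap",
    "permutation_interaction_p",
]

BAND_COLORS = {"red": "#d62728", "yellow": "#ffd92f", "green": "#2ca02c",
               "blue": "#1f77b4"}


@dataclass
class AnovaResult:
    """Two-way ANOVA summary for one response."""

    p_genotype: float
    p_age: float
    p_interaction: float
    f_genotype: float
    f_age: float
    f_interaction: float
    df_genotype: int
    df_age: int
    df_interaction: int
    df_resid: int
    shapiro_p: float
    posthoc: list = field(default_factory=list)
    ss_type: str = "II"

    def p_values(self) -> dict:
        return {"genotype": self.p_genotype, "age": self.p_age,
                "interaction": self.p_interaction}


def _check_cells(table: pd.DataFrame, genotype_col: str, age_col: str) -> None:
    counts = table.groupby([genotype_col, age_col], observed=True).size()
    genos = table[genotype_col].unique()
    ages = table[age_col].unique()
    for g in genos:
        for a in ages:
            if (g, a) not in counts.index:
                raise ValueError(
                    f"empty cell (genotype={g}, age={a}): interaction inestimable")


def fit_two_way(table: pd.DataFrame, response: str, *,
                genotype_col: str = "genotype",
                age_col: str = "age") -> AnovaResult:
    """OLS fit of ``response ~ genotype * age`` (age categorical).

    Type-II sums of squares for the main effects; the interaction term
    comes from the full model.  Residual normality is assessed with the
    Shapiro–Wilk test.  An empty (genotype, age) cell raises
    ``ValueError`` naming the cell.
    """
    _check_cells(table, genotype_col, age_col)
    df = table[[response, genotype_col, age_col]].rename(
        columns={response: "_y", genotype_col: "_g", age_col: "_a"})
    model = smf.ols("_y ~ C(_g) * C(_a)", data=df).fit()
    aov = anova_lm(model, typ=2)
    g_row = aov.loc["C(_g)"]
    a_row = aov.loc["C(_a)"]
    i_row = aov.loc["C(_g):C(_a)"]
    shapiro_p = float(stats.shapiro(model.resid).pvalue)
    return AnovaResult(
        p_genotype=float(g_row["PR(>F)"]), p_age=float(a_row["PR(>F)"]),
        p_interaction=float(i_row["PR(>F)"]),
        f_genotype=float(g_row["F"]), f_age=float(a_row["F"]),
        f_interaction=float(i_row["F"]),
        df_genotype=int(g_row["df"]), df_age=int(a_row["df"]),
        df_interaction=int(i_row["df"]),
        df_resid=int(aov.loc["Residual", "df"]),
        shapiro_p=shapiro_p,
    )


def posthoc(table: pd.DataFrame, response: str, *,
            genotype_col: str = "genotype", age_col: str = "age",
            adjust: str = "bonferroni") -> list[dict]:
    """Welch two-sample genotype contrasts within each age.

    ``adjust="bonferroni"`` multiplies each raw p by the number of
    contrasts (capped at 1); ``adjust="none"`` leaves them raw — the
    convention for station-wise profile comparisons where the original
    per-station inference is preserved.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError("adjust must be 'bonferroni' or 'none'")
    genos = sorted(table[genotype_col].unique())
    if len(genos) != 2:
        raise ValueError("post-hoc contrasts need exactly two genotypes")
    ages = sorted(table[age_col].unique())
    raws = []
    for a in ages:
        sub = table[table[age_col] == a]
        y0 = sub.loc[sub[genotype_col] == genos[0], response]
        y1 = sub.loc[sub[genotype_col] == genos[1], response]
        t = stats.ttest_ind(y1, y0, equal_var=False)
        raws.append({"contrast": f"{genos[1]}-vs-{genos[0]} @ {a}",
                     "estimate": float(y1.mean() - y0.mean()),
                     "p_raw": float(t.pvalue)})
    k = len(raws)
    for r in raws:
        r["p_adjusted"] = min(1.0, r["p_raw"] * k) if adjust == "bonferroni" \
            else r["p_raw"]
        r["method"] = f"welch-t, {adjust}"
    return raws


def positional_analysis(profiles: pd.DataFrame, responses: list[str], *,
                        station_col: str = "position",
                        genotype_col: str = "genotype",
                        age_col: str = "age"
                        ) -> tuple[dict[str, pd.DataFrame], dict[str, float]]:
    """Independent two-way ANOVA at each percent-length station.

    ``profiles`` is long-form: one row per (specimen, station) with the
    response columns.  No cross-station p adjustment is applied.
    Returns per-response station tables (p and F per effect, Shapiro p)
    and the median Shapiro–Wilk p across stations per response.
    """
    results: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    stations = np.sort(profiles[station_col].unique())
    for resp in responses:
        rows = []
        for s in stations:
            sub = profiles[profiles[station_col] == s]
            r = fit_two_way(sub, resp, genotype_col=genotype_col, age_col=age_col)
            rows.append({"position": s, "p_genotype": r.p_genotype,
                         "p_age": r.p_age, "p_interaction": r.p_interaction,
                         "f_genotype": r.f_genotype, "f_age": r.f_age,
                         "f_interaction": r.f_interaction,
                         "shapiro_p": r.shapiro_p})
        tab = pd.DataFrame(rows)
        results[resp] = tab
        medians[resp] = float(tab["shapiro_p"].median())
    return results, medians


def p_band(p: float) -> str:
    """Four-colour significance class of a p-value.

    red p ≤ 0.001; yellow 0.001 < p ≤ 0.01; green 0.01 < p ≤ 0.05
    (0.05 itself is green); blue p > 0.05.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p <= 0.001:
        return "red"
    if p <= 0.01:
        return "yellow"
    if p <= 0.05:
        return "green"
    return "blue"


def significance_heatmap(station_results: dict[str, pd.DataFrame]
                         ) -> pd.DataFrame:
    """Band the genotype (G) and interaction (GxA) effects per station.

    Returns a long DataFrame with columns response, position, effect
    ∈ {G, GxA}, p, band.
    """
    rows = []
    for resp, tab in station_results.items():
        for _, r in tab.iterrows():
            for eff, col in (("G", "p_genotype"), ("GxA", "p_interaction")):
                rows.append({"response": resp, "position": r["position"],
                             "effect": eff, "p": r[col],
                             "band": p_band(r[col])})
    return pd.DataFrame(rows)


def render_heatmap(bands: pd.DataFrame, path: str) -> None:
    """Render the banded map (one row per response x effect) to SVG/PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    order = ["red", "yellow", "green", "blue"]
    cmap = ListedColormap([BAND_COLORS[c] for c in order])
    keys = sorted({(r, e) for r, e in zip(bands["response"], bands["effect"])})
    positions = np.sort(bands["position"].unique())
    img = np.zeros((len(keys), len(positions)), dtype=int)
    for i, (resp, eff) in enumerate(keys):
        sub = bands[(bands["response"] == resp) & (bands["effect"] == eff)]
        sub = sub.set_index("position").reindex(positions)
        img[i] = [order.index(b) for b in sub["band"]]
    fig, ax = plt.subplots(figsize=(10, 0.5 * len(keys) + 1.5))
    ax.imshow(img, aspect="auto", cmap=cmap, vmin=0, vmax=3,
              extent=[positions.min(), positions.max(), len(keys), 0])
    ax.set_yticks(np.arange(len(keys)) + 0.5)
    ax.set_yticklabels([f"{r} ({e})" for r, e in keys])
    ax.set_xlabel("% of bone length")
    ax.set_title("significance bands: red ≤0.001, yellow ≤0.01, "
                 "green ≤0.05, blue >0.05")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# ---------------------------------------------------------------------------
# permutation reference for the interaction test
# ---------------------------------------------------------------------------

def permutation_interaction_p(table: pd.DataFrame, response: str, *,
                              genotype_col: str = "genotype",
                              age_col: str = "age",
                              n_permutations: int = 100_000,
                              seed: int = 0) -> float:
    """Permutation p-value for the interaction F statistic.

    Responses are freely permuted across all observations (exchangeable
    under the global null) and the interaction F — extra sum of squares
    of the full cell-means model over the additive model — is
    recomputed for every permutation in one vectorised pass.  Reported
    with the add-one correction ``(1 + #{F* ≥ F}) / (1 + B)``.
    """
    y = table[response].to_numpy(dtype=float)
    g = pd.Categorical(table[genotype_col]).codes
    a = pd.Categorical(table[age_col]).codes
    n = len(y)
    cells = pd.Categorical(list(zip(g, a))).codes
    X_full = np.eye(len(np.unique(cells)))[cells]
    X_red = np.column_stack([np.ones(n),
                             np.eye(len(np.unique(g)))[g][:, 1:],
                             np.eye(len(np.unique(a)))[a][:, 1:]])

    def hat(X):
        return X @ np.linalg.pinv(X.T @ X) @ X.T

    Hf, Hr = hat(X_full), hat(X_red)
    df_inter = X_full.shape[1] - X_red.shape[1]
    df_resid = n - X_full.shape[1]

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(y[:, None], (1, n_permutations)), axis=0)

    def f_stats(Y):
        yy = np.einsum("ij,ij->j", Y, Y)
        rss_f = yy - np.einsum("ij,ij->j", Y, Hf @ Y)
        rss_r = yy - np.einsum("ij,ij->j", Y, Hr @ Y)
        return ((rss_r - rss_f) / df_inter) / (rss_f / df_resid)

    f_obs = f_stats(y[:, None])[0]
    f_perm = f_stats(perms)
    return float((1 + np.count_nonzero(f_perm >= f_obs)) / (1 + n_permutations))
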