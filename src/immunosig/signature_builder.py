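"""Response-signature construction on the batch-adjusted bulk training cohort.

Workflow: empirical-Bayes batch adjustment; per-gene t-test of NPD vs
PD yielding the NPD-up gene list Gx; intersection of Gx with each
subgroup marker list; union of the four intersections into the
comprehensive signature.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from immunosig.errors import ValidationError
from immunosig.io_formats import BulkCohort, GeneSignature


# ---------------------------------------------------------------------------
# Batch adjustment (parametric empirical-Bayes location/scale)
# ---------------------------------------------------------------------------


def combat_adjust(cohort: BulkCohort, max_iter: int = 100, tol: float = 1e-4) -> BulkCohort:
    """Remove additive and multiplicative batch effects per gene.

    Standardize each gene with its grand mean and pooled variance,
    estimate per-batch location/scale on the standardized data, shrink
    both toward parametric priors across genes (normal prior on
    location, inverse-gamma on scale), remove the shrunken effects and
    restore the grand scale. A single-batch cohort is returned
    unchanged with a warning.
    """
    batches = cohort.clinical["batch"]
    batch_names = list(pd.unique(batches))
    if len(batch_names) < 2:
        warnings.warn("single batch; returning cohort unchanged")
        return cohort
    sizes = batches.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValidationError(f"batches with a single sample: {list(small.index)}")

    x = cohort.expression.to_numpy(dtype=float).T  # genes x samples
    n_genes, n_samples = x.shape
    masks = {b: (batches == b).to_numpy() for b in batch_names}
    n_i = np.array([masks[b].sum() for b in batch_names], dtype=float)

    batch_means = np.stack([x[:, masks[b]].mean(axis=1) for b in batch_names])
    grand_mean = (n_i[:, None] * batch_means).sum(axis=0) / n_samples
    fitted = np.zeros_like(x)
    for k, b in enumerate(batch_names):
        fitted[:, masks[b]] = batch_means[k][:, None]
    var_pooled = ((x - fitted) ** 2).mean(axis=1)
    var_pooled = np.where(var_pooled <= 0, 1e-8, var_pooled)
    sd_pooled = np.sqrt(var_pooled)

    s = (x - grand_mean[:, None]) / sd_pooled[:, None]

    adjusted = np.empty_like(s)
    for k, b in enumerate(batch_names):
        sb = s[:, masks[b]]
        n_b = sb.shape[1]
        gamma_hat = sb.mean(axis=1)
        delta_hat = sb.var(axis=1, ddof=1)
        delta_hat = np.where(delta_hat <= 0, 1e-8, delta_hat)

        gamma_bar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        a_prior, b_prior = _inverse_gamma_moments(delta_hat)

        gamma_star, delta_star = gamma_hat.copy(), delta_hat.copy()
        for _ in range(max_iter):
            g_new = (t2 * n_b * gamma_hat + delta_star * gamma_bar) / (
                t2 * n_b + delta_star
            )
            sum2 = ((sb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b_prior) / (n_b / 2.0 + a_prior - 1.0)
            d_new = np.where(d_new <= 0, delta_star, d_new)
            change = max(
                np.abs(g_new - gamma_star).max(), np.abs(d_new - delta_star).max()
            )
            gamma_star, delta_star = g_new, d_new
            if change < tol:
                break
        adjusted[:, masks[b]] = (sb - gamma_star[:, None]) / np.sqrt(
            delta_star[:, None]
        )

    out = adjusted * sd_pooled[:, None] + grand_mean[:, None]
    expression = pd.DataFrame(
        out.T, index=cohort.expression.index, columns=cohort.expression.columns
    )
    return BulkCohort(expression=expression, clinical=cohort.clinical.copy())


def _inverse_gamma_moments(delta_hat: np.ndarray) -> tuple[float, float]:
    """Method-of-moments inverse-gamma hyperparameters for the scale prior."""
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    if s2 <= 0:
        return 2.0, m
    a = (2 * s2 + m**2) / s2
    b = (m * s2 + m**3) / s2
    return a, b


# ---------------------------------------------------------------------------
# Gx derivation and signature assembly
# ---------------------------------------------------------------------------


def derive_gx(
    cohort: BulkCohort,
    alpha: float = 0.05,
    direction: str = "npd_up",
) -> tuple[pd.DataFrame, GeneSignature]:
    """Per-gene Welch t-test of NPD vs PD; Gx = significant NPD-up genes.

    ``direction="both"`` admits significant genes of either sign.
    Returns (full DEG table, Gx signature).
    """
    response = cohort.response
    npd = cohort.expression[response == "NPD"].to_numpy(dtype=float)
    pd_ = cohort.expression[response == "PD"].to_numpy(dtype=float)
    if npd.shape[0] < 2 or pd_.shape[0] < 2:
        raise ValidationError("each response class needs >= 2 samples")

    t_stat, p_val = scipy.stats.ttest_ind(npd, pd_, axis=0, equal_var=False)
    mean_npd = npd.mean(axis=0)
    mean_pd = pd_.mean(axis=0)
    table = pd.DataFrame(
        {
            "gene": cohort.genes,
            "mean_NPD": mean_npd,
            "mean_PD": mean_pd,
            "t_statistic": t_stat,
            "p_value": p_val,
            "direction": np.sign(mean_npd - mean_pd).astype(int),
        }
    )
    sig = table["p_value"] < alpha
    if direction == "npd_up":
        sig &= table["direction"] > 0
    elif direction != "both":
        raise ValidationError(f"unknown direction {direction!r}")
    gx_genes = tuple(table.loc[sig, "gene"])
    gx = GeneSignature(
        "Gx",
        gx_genes,
        provenance={"alpha": alpha, "direction": direction, "test": "welch_t"},
    )
    return table, gx


def intersect_signature(
    gx: GeneSignature, subgroup_markers: GeneSignature, name: str
) -> GeneSignature:
    """Intersection of Gx with one subgroup marker list, in Gx order."""
    marker_set = set(subgroup_markers.genes)
    genes = tuple(g for g in gx.genes if g in marker_set)
    if not genes:
        warnings.warn(f"signature {name!r} is empty (disjoint inputs)")
    return GeneSignature(
        name,
        genes,
        provenance={"parents": [gx.name, subgroup_markers.name]},
    )


def combine_signatures(
    signatures: list[GeneSignature], name: str = "Comprehensive.sig"
) -> GeneSignature:
    """De-duplicated union of component signatures, first-seen order."""
    if not signatures or all(len(s) == 0 for s in signatures):
        raise ValidationError("all component signatures are empty")
    genes: list[str] = []
    seen: set[str] = set()
    for sig in signatures:
        for g in sig.genes:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    return GeneSignature(
        name, tuple(genes), provenance={"parents": [s.name for s in signatures]}
    )


def build_signatures(
    train: BulkCohort,
    subgroup_markers: dict[str, GeneSignature],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, GeneSignature]]:
    """Full assembly: Gx, the four intersections, and their union.

    ``subgroup_markers`` maps signature names (e.g. "MM.sig") to
    subgroup marker lists. Operates on the training cohort only; the
    caller is responsible for withholding the test partition.
    """
    deg_table, gx = derive_gx(train, alpha=alpha)
    out: dict[str, GeneSignature] = {}
    for name, markers in subgroup_markers.items():
        out[name] = intersect_signature(gx, markers, name)
    out["Comprehensive.sig"] = combine_signatures(list(out.values()))
    out["Gx"] = gx
    return deg_table, out
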