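"""Model-based expression adjustment and partial-correlation networks."""

import numpy as np
import pandas as pd
import pytest

from nbdex.glm import fit_nb_glm
from nbdex.models import DesignInfo
from nbdex.network import adjust_expression, build_network, edge_table, partial_correlations


def _exact_corr_data(Sigma, n=40, seed=0):
    """Rows with empirical covariance exactly Sigma (orthonormal basis trick)."""
    rng = np.random.default_rng(seed)
    p = Sigma.shape[0]
    Z = rng.normal(size=(p, n))
    Z -= Z.mean(axis=1, keepdims=True)
    # orthonormalise rows, then colour by the Cholesky factor
    Q, _ = np.linalg.qr(Z.T)
    B = Q.T[:p] * np.sqrt(n)
    L = np.linalg.cholesky(Sigma)
    return L @ B


def brute_force_pcor(X):
    """Regress-out-and-correlate definition of partial correlation."""
    vals = np.asarray(X, dtype=float)
    p = vals.shape[0]
    out = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            others = [k for k in range(p) if k not in (i, j)]
            Z = np.column_stack([np.ones(vals.shape[1]), vals[others].T])
            ri = vals[i] - Z @ np.linalg.lstsq(Z, vals[i], rcond=None)[0]
            rj = vals[j] - Z @ np.linalg.lstsq(Z, vals[j], rcond=None)[0]
            out[i, j] = out[j, i] = np.corrcoef(ri, rj)[0, 1]
    return out


class TestPartialCorrelations:
    def test_three_gene_closed_form(self):
        r12, r13, r23 = 0.5, 0.6, 0.3
        Sigma = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1.0]])
        X = pd.DataFrame(_exact_corr_data(Sigma))
        pcor = partial_correlations(X).to_numpy()
        expected = (r12 - r13 * r23) / np.sqrt((1 - r13**2) * (1 - r23**2))
        assert pcor[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_matches_regress_and_correlate(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(6, 30)))
        pcor = partial_correlations(X).to_numpy()
        ref = brute_force_pcor(X.to_numpy())
        assert np.allclose(pcor, ref, atol=1e-8)

    def test_independent_genes_near_zero(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(3, 4000)))
        pcor = partial_correlations(X).to_numpy()
        off = pcor[~np.eye(3, dtype=bool)]
        assert np.max(np.abs(off)) < 0.06

    def test_constant_gene_errors(self):
        X = pd.DataFrame(np.vstack([np.ones(10), np.arange(10), np.arange(10) ** 2]))
        with pytest.raises(ValueError, match="constant"):
            partial_correlations(X)

    def test_pseudoinverse_handles_more_genes_than_samples(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(30, 10)))  # p > n
        pcor = partial_correlations(X).to_numpy()
        assert np.all(np.isfinite(pcor))
        assert np.allclose(pcor, pcor.T)

    def test_pseudoinverse_reduces_to_inverse_when_well_conditioned(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(5, 500)))
        corr = np.corrcoef(X.to_numpy())
        P = np.linalg.inv(corr)
        d = np.sqrt(np.diag(P))
        expected = -P / np.outer(d, d)
        np.fill_diagonal(expected, 1.0)
        assert np.allclose(partial_correlations(X).to_numpy(), expected, atol=1e-10)


class TestBuildNetwork:
    def _pcor(self, v):
        return pd.DataFrame(
            [[1.0, v, 0.0], [v, 1.0, 0.0], [0.0, 0.0, 1.0]], index=list("abc"), columns=list("abc")
        )

    def test_threshold_is_strict(self):
        assert build_network(self._pcor(0.8)).number_of_edges() == 0
        g = build_network(self._pcor(0.81))
        assert g.number_of_edges() == 1
        assert g.edges[("a", "b")]["sign"] == "+"

    def test_negative_edges_signed(self):
        g = build_network(self._pcor(-0.9))
        assert g.edges[("a", "b")]["sign"] == "-"

    def test_identity_matrix_gives_empty_network(self):
        assert build_network(self._pcor(0.0)).number_of_edges() == 0

    def test_edges_invariant_under_gene_reordering(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(6, 40)), index=list("abcdef"))
        p1 = partial_correlations(X)
        perm = list("fbdace")
        p2 = partial_correlations(X.loc[perm])
        g1 = build_network(p1, threshold=0.1)
        g2 = build_network(p2, threshold=0.1)
        e1 = {frozenset(e) for e in g1.edges}
        e2 = {frozenset(e) for e in g2.edges}
        assert e1 == e2

    def test_edge_table_columns(self):
        tab = edge_table(build_network(self._pcor(0.9)))
        assert list(tab.columns) == ["gene_a", "gene_b", "pcor", "sign"]
        assert len(tab) == 1


class TestAdjustExpression:
    def _fit_gene(self, y, design, terms):
        info = DesignInfo.from_frame(design, terms)
        X = info.encode(design)
        fit = fit_nb_glm(y, X, np.zeros(len(y)), 0.05, colnames=info.colnames)
        fit.design_info = info
        return fit

    def test_diet_only_model_reproduces_working_response(self):
        rng = np.random.default_rng(8)
        design = pd.DataFrame({"diet": ["CTRL"] * 10 + ["REST"] * 10})
        mu = np.exp(4.0 + 0.5 * (design["diet"] == "REST").to_numpy(float))
        y = rng.poisson(rng.gamma(20.0, 0.05 * mu)).astype(float)
        fit = self._fit_gene(y, design, ["diet"])
        adj = adjust_expression({"g": fit}).loc["g"].to_numpy()
        working = (fit.eta - fit.colnames.index("Intercept") * 0) + (y - fit.mu) / fit.mu
        # equal up to the intercept column (removed from the adjustment)
        assert np.allclose(adj - working, -fit.beta[0], atol=1e-10)

    def test_shared_batch_effect_decorrelated(self):
        """Two null genes driven by one batch effect: raw correlation is
        high, adjusted correlation is near zero."""
        rng = np.random.default_rng(9)
        n = 60
        batch = np.repeat(["b1", "b2"], n // 2)
        design = pd.DataFrame({"diet": ["CTRL", "REST"] * (n // 2), "batch": batch})
        shift = np.where(batch == "b2", 1.2, 0.0)
        adj_rows = {}
        raw = []
        for gid in ("g1", "g2"):
            mu = np.exp(4.0 + shift)
            y = rng.poisson(rng.gamma(20.0, 0.05 * mu)).astype(float)
            raw.append(np.log(y + 1))
            adj_rows[gid] = self._fit_gene(y, design, ["diet", "batch"])
        adj = adjust_expression(adj_rows)
        raw_corr = np.corrcoef(raw[0], raw[1])[0, 1]
        adj_corr = np.corrcoef(adj.loc["g1"], adj.loc["g2"])[0, 1]
        assert raw_corr > 0.8
        assert abs(adj_corr) < 0.35

    def test_adjusted_values_uncorrelated_with_batch(self):
        rng = np.random.default_rng(10)
        n = 80
        batch = np.repeat(["b1", "b2"], n // 2)
        design = pd.DataFrame({"diet": ["CTRL", "REST"] * (n // 2), "batch": batch})
        mu = np.exp(4.0 + np.where(batch == "b2", 0.8, 0.0))
        y = rng.poisson(rng.gamma(20.0, 0.05 * mu)).astype(float)
        fit = self._fit_gene(y, design, ["diet", "batch"])
        adj = adjust_expression({"g": fit}).loc["g"].to_numpy()
        diff = adj[batch == "b2"].mean() - adj[batch == "b1"].mean()
        assert abs(diff) < 0.1  # batch component removed

    def test_nonconverged_fits_dropped(self):
        rng = np.random.default_rng(11)
        design = pd.DataFrame({"diet": ["CTRL"] * 5 + ["REST"] * 5})
        y = rng.poisson(50.0, 10).astype(float)
        fit = self._fit_gene(y, design, ["diet"])
        bad = self._fit_gene(y, design, ["diet"])
        bad.converged = False
        adj = adjust_expression({"ok": fit, "bad": bad})
        assert list(adj.index) == ["ok"]
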