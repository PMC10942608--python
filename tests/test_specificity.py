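import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allelospec.specificity import (
    all_pairwise_de,
    broad_specific_genes,
    broad_specific_peaks,
    downsample_counts,
    narrow_specific_genes,
    narrow_specific_peaks,
    pairwise_de_test,
    welch_p,
)

from conftest import make_table


def tpm_frame(rows, cell_types=("MN", "CM", "HP", "PP", "SKM", "RPE")):
    return pd.DataFrame(rows, columns=list(cell_types),
                        index=[f"g{i}" for i in range(len(rows))])


class TestNarrowSpecificGenes:
    def test_single_expressed_cell_type(self):
        tpm = tpm_frame([[0.5, 0.2, 0.9, 0.3, 0.1, 3.0]])
        call = narrow_specific_genes(tpm, high=1.0)
        assert call.calls.loc["g0", "specific_to"] == "RPE"

    def test_two_expressed_cell_types_not_specific(self):
        tpm = tpm_frame([[0.5, 1.2, 3.0, 0.1, 0.1, 0.1]])
        call = narrow_specific_genes(tpm, high=1.0)
        assert call.calls.loc["g0", "specific_to"] == ""

    def test_all_zero_not_specific(self):
        tpm = tpm_frame([[0.0] * 6])
        assert narrow_specific_genes(tpm).calls.loc["g0", "specific_to"] == ""

    def test_monotone_in_high_threshold(self, rng):
        tpm = tpm_frame(rng.gamma(0.5, 4.0, size=(300, 6)))
        at1 = narrow_specific_genes(tpm, high=1.0).calls["specific_to"]
        at5 = narrow_specific_genes(tpm, high=5.0).calls["specific_to"]
        specific_at_5 = set(at5.index[at5 != ""])
        specific_at_1 = set(at1.index[at1 != ""])
        assert specific_at_5 <= specific_at_1


class TestPairwiseDe:
    def test_identical_groups_p_one(self):
        counts = pd.DataFrame(
            [[10, 10, 10, 10, 10, 10]], index=["g0"],
            columns=[f"s{i}" for i in range(6)],
        )
        meta = pd.DataFrame({
            "cell_type": ["MN"] * 3 + ["CM"] * 3,
        }, index=counts.columns)
        p = pairwise_de_test(counts, meta, "MN", "CM")
        assert p["g0"] == 1.0

    def test_matches_textbook_welch(self):
        # oracle: direct Welch t statistic + Satterthwaite df on the
        # transformed values
        a = np.array([[10.0, 12.0, 11.0]])
        b = np.array([[100.0, 95.0, 105.0]])
        p = welch_p(a, b)[0]
        va, vb = a.var(ddof=1), b.var(ddof=1)
        t = (a.mean() - b.mean()) / np.sqrt(va / 3 + vb / 3)
        df = (va / 3 + vb / 3) ** 2 / (
            (va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
        expected = 2 * stats.t.sf(abs(t), df)
        assert p == pytest.approx(expected, abs=1e-10)
        scipy_p = stats.ttest_ind(a[0], b[0], equal_var=False).pvalue
        assert p == pytest.approx(scipy_p, abs=1e-12)

    def test_single_sample_group_rejected(self):
        counts = pd.DataFrame([[1, 2, 3]], index=["g0"],
                              columns=["s0", "s1", "s2"])
        meta = pd.DataFrame({"cell_type": ["MN", "MN", "CM"]},
                            index=counts.columns)
        with pytest.raises(ValueError, match=">= 2 samples"):
            pairwise_de_test(counts, meta, "MN", "CM")


class TestBroadSpecificGenes:
    @staticmethod
    def _pairwise(fdrs, cell_types=("MN", "CM", "HP")):
        """Build a tidy pairwise frame for one gene from a dict of fdrs."""
        rows = []
        for (a, b), q in fdrs.items():
            rows.append(("g0", a, b, q, q))
            rows.append(("g0", b, a, q, q))
        return pd.DataFrame(rows, columns=["gene", "cell_type", "other",
                                           "p", "fdr"])

    def test_de_against_all_others_is_specific(self):
        pw = self._pairwise({("MN", "CM"): 0.01, ("MN", "HP"): 0.01,
                             ("CM", "HP"): 0.9})
        call = broad_specific_genes({"ref_human": pw, "ref_chimp": pw})
        assert call.calls.loc["g0", "specific_to"] == "MN"

    def test_failing_one_pair_is_not_specific(self):
        pw = self._pairwise({("MN", "CM"): 0.01, ("MN", "HP"): 0.2,
                             ("CM", "HP"): 0.9})
        call = broad_specific_genes({"ref_human": pw, "ref_chimp": pw})
        assert call.calls.loc["g0", "specific_to"] == ""

    def test_must_hold_under_both_references(self):
        good = self._pairwise({("MN", "CM"): 0.01, ("MN", "HP"): 0.01,
                               ("CM", "HP"): 0.9})
        bad = self._pairwise({("MN", "CM"): 0.01, ("MN", "HP"): 0.5,
                              ("CM", "HP"): 0.9})
        call = broad_specific_genes({"ref_human": good, "ref_chimp": bad})
        assert call.calls.loc["g0", "specific_to"] == ""

    def test_cell_type_exclusion_restores_specificity(self):
        pw = self._pairwise({
            ("MN", "CM"): 0.01, ("MN", "HP"): 0.01, ("MN", "SKM"): 0.5,
            ("CM", "HP"): 0.9, ("CM", "SKM"): 0.9, ("HP", "SKM"): 0.9,
        })
        with_skm = broad_specific_genes({"ref_human": pw, "ref_chimp": pw})
        no_skm = broad_specific_genes({"ref_human": pw, "ref_chimp": pw},
                                      exclude=("SKM",))
        assert with_skm.calls.loc["g0", "specific_to"] == ""
        assert no_skm.calls.loc["g0", "specific_to"] == "MN"

    def test_alpha_one_marks_everything_alpha_zero_nothing(self):
        pw = self._pairwise({("MN", "CM"): 0.5, ("MN", "HP"): 0.5,
                             ("CM", "HP"): 0.5})
        refs = {"ref_human": pw, "ref_chimp": pw}
        none = broad_specific_genes(refs, alpha=0.0).calls["specific_to"]
        assert (none == "").all()
        # at alpha=1 every cell type passes every pair, so no gene is
        # uniquely assignable (ambiguous rows stay uncalled)
        all_pass = broad_specific_genes(refs, alpha=1.0)
        assert (all_pass.calls["specific_to"] == "").all()

    def test_missing_pair_is_error(self):
        pw = self._pairwise({("MN", "CM"): 0.01})
        pw = pd.concat([pw, self._pairwise({("MN", "HP"): 0.01}).iloc[:1]])
        with pytest.raises(ValueError, match="missing pairwise"):
            broad_specific_genes({"ref_human": pw})


class TestDownsampleCounts:
    def _table(self, rng):
        h = rng.integers(0, 200, size=(50, 2))
        c = rng.integers(0, 200, size=(50, 2))
        return make_table(h, c, cell_types=["MN", "MN"])

    def test_identity_at_current_total(self, rng):
        table = self._table(rng)
        total = int(table.human["s0"].sum() + table.chimp["s0"].sum())
        total1 = int(table.human["s1"].sum() + table.chimp["s1"].sum())
        out = downsample_counts(table, min(total, total1), seed=0)
        tgt = min(total, total1)
        sums = out.human.sum() + out.chimp.sum()
        assert (sums == tgt).all()

    def test_conservation_exact(self, rng):
        table = self._table(rng)
        out = downsample_counts(table, 500, seed=1)
        assert ((out.human.sum() + out.chimp.sum()) == 500).all()
        assert (out.human.to_numpy() <= table.human.to_numpy()).all()
        assert (out.chimp.to_numpy() <= table.chimp.to_numpy()).all()

    def test_target_above_total_names_sample(self, rng):
        table = self._table(rng)
        with pytest.raises(ValueError, match="s0|s1"):
            downsample_counts(table, 10 ** 9, seed=0)

    def test_proportions_preserved_in_expectation(self, rng):
        table = make_table([[4000], [1000]], [[2000], [1000]],
                           cell_types=["MN"])
        props = []
        for seed in range(100):
            out = downsample_counts(table, 800, seed=seed)
            props.append(out.human.iloc[0, 0] / 800)
        p_true = 4000 / 8000
        se = np.sqrt(p_true * (1 - p_true) / 800 / 100)
        assert abs(np.mean(props) - p_true) < 3 * se


class TestBroadSpecificPeaks:
    def test_clear_winner(self):
        cpm = pd.DataFrame([[40.0, 10.0, 10.0, 10.0, 10.0]], index=["p0"],
                           columns=list("ABCDE"))
        call = broad_specific_peaks(cpm, min_abs_lfc=0.5)
        assert call.calls.loc["p0", "specific_to"] == "A"

    def test_near_tie_blocks_specificity(self):
        # |log2(41/31)| = 0.403 < 0.5
        cpm = pd.DataFrame([[40.0, 30.0, 10.0, 10.0, 10.0]], index=["p0"],
                           columns=list("ABCDE"))
        call = broad_specific_peaks(cpm, min_abs_lfc=0.5)
        assert call.calls.loc["p0", "specific_to"] == ""

    def test_flat_profile_never_specific(self):
        cpm = pd.DataFrame([[10.0] * 5], index=["p0"], columns=list("ABCDE"))
        assert broad_specific_peaks(cpm).calls.loc["p0", "specific_to"] == ""


class TestNarrowSpecificPeaks:
    @pytest.mark.parametrize("row, expected", [
        ([True, False, False], "A"),
        ([True, True, True], ""),
        ([False, False, False], ""),
    ])
    def test_called_in_exactly_one(self, row, expected):
        called = pd.DataFrame([row], index=["p0"], columns=list("ABC"))
        assert narrow_specific_peaks(called).calls.loc["p0", "specific_to"] \
            == expected


def test_broad_specificity_recovers_simulated_truth(mixed_sim):
    # genes made cell-type-specific in total expression should be found
    rng = np.random.default_rng(77)
    table = mixed_sim["rna"][0]
    total = (table.human + table.chimp).astype(float)
    genes = total.index[:80]
    truth = {}
    for i, g in enumerate(genes):
        ct = table.cell_types[i % len(table.cell_types)]
        boost = table.meta["cell_type"] == ct
        total.loc[g, boost.values] *= 8.0
        truth[g] = ct
    pw = all_pairwise_de(total, table.meta)
    calls = broad_specific_genes({"ref_human": pw}).calls["specific_to"]
    hits = calls.loc[genes]
    recall = np.mean([hits[g] == truth[g] for g in genes])
    flagged = calls[calls != ""]
    precision = np.mean([g in truth and truth[g] == flagged[g]
                         for g in flagged.index]) if len(flagged) else 1.0
    assert recall >= 0.8
    assert precision >= 0.9
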