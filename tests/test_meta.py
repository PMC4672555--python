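"""Stouffer meta-analysis, the comparative score and candidate selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from screenkit import meta


def _stats_from_z(z: pd.DataFrame, lfc=None, p=None) -> pd.DataFrame:
    """Build a tidy stats table from a hairpin x line z matrix."""
    rows = []
    for hp in z.index:
        for ln in z.columns:
            rows.append(
                {
                    "hairpin_id": hp,
                    "line": ln,
                    "z": z.loc[hp, ln],
                    "log2fc": (lfc.loc[hp, ln] if lfc is not None else z.loc[hp, ln]),
                    "t": z.loc[hp, ln],
                    "p": (
                        p.loc[hp, ln]
                        if p is not None
                        else 2 * sps.norm.sf(abs(z.loc[hp, ln]))
                    ),
                }
            )
    return pd.DataFrame(rows)


GROUPS = {"I1": "IBC", "I2": "IBC", "N1": "nonIBC", "N2": "nonIBC"}


class TestStouffer:
    def test_single_value_identity(self):
        assert meta.stouffer_z([1.7]) == pytest.approx(1.7)

    def test_known_example(self):
        # z = (-2, -2, -2, -2) -> Z = -8/2 = -4
        assert meta.stouffer_z([-2.0] * 4) == pytest.approx(-4.0)

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            meta.stouffer_z([])
        with pytest.raises(ValueError):
            meta.stouffer_z([1.0, np.nan])

    def test_null_preserved(self, rng):
        # Z over k N(0,1) inputs stays N(0,1)
        z = rng.normal(size=(4000, 5))
        pooled = z.sum(axis=1) / np.sqrt(5)
        assert sps.kstest(pooled, "norm").pvalue > 0.01


class TestComparative:
    def test_hand_computed_scores(self):
        z = pd.DataFrame(
            {"I1": [-3.0, 0.0], "I2": [-2.0, 0.5], "N1": [0.0, 0.2], "N2": [1.0, -0.3]},
            index=["h1", "h2"],
        )
        comp = meta.ibc_comparative(_stats_from_z(z), GROUPS)
        z_a = (-3.0 - 2.0) / np.sqrt(2)
        z_b = (0.0 + 1.0) / np.sqrt(2)
        z_c = (z_a - z_b) / np.sqrt(2)
        assert comp.loc["h1", "z_a"] == pytest.approx(z_a)
        assert comp.loc["h1", "z_comp"] == pytest.approx(z_c)
        assert comp.loc["h1", "p_comb"] == pytest.approx(2 * sps.norm.sf(abs(z_c)))
        assert bool(comp.loc["h1", "passes_cutoff"])
        assert not bool(comp.loc["h2", "passes_cutoff"])

    def test_threshold_boundary_1p96(self):
        # the exact two-tailed 0.05 point is z = 1.959964...; -1.95 falls
        # short (p = 0.051) while -1.96 just clears the cutoff (p = 0.049996)
        for zc, expect in ((-1.95, False), (-1.96, True)):
            z_a = zc * np.sqrt(2)
            z = pd.DataFrame(
                {"I1": [z_a * np.sqrt(2) / 2], "I2": [z_a * np.sqrt(2) / 2],
                 "N1": [0.0], "N2": [0.0]},
                index=["h"],
            )
            comp = meta.ibc_comparative(_stats_from_z(z), GROUPS)
            assert comp.loc["h", "z_comp"] == pytest.approx(zc, abs=1e-9)
            assert bool(comp.loc["h", "passes_cutoff"]) is expect

    def test_enrichment_direction_not_flagged(self):
        z = pd.DataFrame(
            {"I1": [3.0], "I2": [3.0], "N1": [0.0], "N2": [0.0]}, index=["h"]
        )
        comp = meta.ibc_comparative(_stats_from_z(z), GROUPS)
        assert comp.loc["h", "p_comb"] < 0.05
        assert not bool(comp.loc["h", "passes_cutoff"])

    def test_missing_line_z_drops_hairpin(self):
        z = pd.DataFrame(
            {"I1": [-2.0, np.nan], "I2": [-2.0, -2.0], "N1": [0.0, 0.0],
             "N2": [0.0, 0.0]},
            index=["h1", "h2"],
        )
        comp = meta.ibc_comparative(_stats_from_z(z), GROUPS)
        assert list(comp.index) == ["h1"]

    def test_absent_group_errors(self):
        z = pd.DataFrame({"I1": [-2.0]}, index=["h"])
        with pytest.raises(ValueError):
            meta.ibc_comparative(_stats_from_z(z), {"I1": "IBC"})


def _brute_force_select(z, lfc, p, groups, library, p_cut=0.05, fc_cut=-1.0):
    """Independent re-implementation of the three clauses, hairpin by hairpin."""
    lines_t = [ln for ln, g in groups.items() if g == "IBC"]
    lines_x = [ln for ln, g in groups.items() if g == "nonTransformed"]
    passing = []
    for hp in z.index:
        za = sum(z.loc[hp, ln] for ln in lines_t) / np.sqrt(len(lines_t))
        lines_b = [ln for ln, g in groups.items() if g == "nonIBC"]
        zb = sum(z.loc[hp, ln] for ln in lines_b) / np.sqrt(len(lines_b))
        zc = (za - zb) / np.sqrt(2)
        c1 = (2 * sps.norm.sf(abs(zc)) < p_cut) and zc < 0
        c2 = all(lfc.loc[hp, ln] <= fc_cut for ln in lines_t)
        c3 = not any(
            (p.loc[hp, ln] < p_cut) and (lfc.loc[hp, ln] < fc_cut) for ln in lines_x
        )
        if c1 and c2 and c3:
            passing.append(hp)
    gene_of = library.set_index("hairpin_id")["gene_id"]
    return set(passing), {gene_of[hp] for hp in passing}


class TestSelectCandidates:
    def _random_inputs(self, seed, n_genes=60, groups=None):
        rng = np.random.default_rng(seed)
        groups = groups or {
            "I1": "IBC", "I2": "IBC", "N1": "nonIBC", "N2": "nonIBC",
            "T1": "nonTransformed",
        }
        hp_ids = [f"h{i}" for i in range(n_genes * 2)]
        library = pd.DataFrame(
            {
                "hairpin_id": hp_ids,
                "gene_id": [f"g{i // 2}" for i in range(n_genes * 2)],
                "guide_seq": ["ACGT"] * (n_genes * 2),
            }
        )
        lines = list(groups)
        z = pd.DataFrame(
            rng.normal(scale=1.5, size=(len(hp_ids), len(lines))),
            index=hp_ids, columns=lines,
        )
        lfc = pd.DataFrame(
            rng.normal(loc=-0.8, scale=0.8, size=z.shape), index=hp_ids, columns=lines
        )
        p = pd.DataFrame(
            rng.uniform(size=z.shape) ** 2, index=hp_ids, columns=lines
        )
        return z, lfc, p, groups, library

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        z, lfc, p, groups, library = self._random_inputs(seed)
        stats_df = _stats_from_z(z, lfc=lfc, p=p)
        comp = meta.ibc_comparative(stats_df, groups)
        genes, passing = meta.select_candidates(comp, stats_df, groups, library)
        exp_hp, exp_genes = _brute_force_select(z, lfc, p, groups, library)
        assert set(passing.index) == exp_hp
        got_genes = set(genes["gene_id"]) if len(genes) else set()
        assert got_genes == exp_genes

    def test_sorted_by_best_z_comp(self, small_stats):
        from screenkit import dropout  # noqa: F401 (fixture already computed)

        cm = small_stats["cm"]
        stats_df = small_stats["stats"]
        groups = cm.line_groups()
        comp = meta.ibc_comparative(stats_df, groups)
        genes, _ = meta.select_candidates(comp, stats_df, groups, small_stats["library"])
        assert genes["z_comp"].is_monotonic_increasing

    def test_recovers_planted_ibc_genes(self, small_stats):
        truth = small_stats["truth"]
        cm = small_stats["cm"]
        stats_df = small_stats["stats"]
        groups = cm.line_groups()
        comp = meta.ibc_comparative(stats_df, groups)
        genes, _ = meta.select_candidates(comp, stats_df, groups, small_stats["library"])
        planted = {
            g for g, lines in truth.essential_map.items()
            if set(lines) == {"IBC1", "IBC2"}
        }
        assert planted
        found = set(genes["gene_id"])
        recall = len(planted & found) / len(planted)
        # non-planted, non-essential genes should rarely slip through
        benign = found - set(truth.essential_map)
        fpr = len(benign) / (small_stats["cfg"].n_genes - len(truth.essential_map))
        assert recall >= 0.8
        assert fpr <= 0.02

    def test_min_hairpins_two_is_stricter(self, small_stats):
        cm = small_stats["cm"]
        stats_df = small_stats["stats"]
        groups = cm.line_groups()
        comp = meta.ibc_comparative(stats_df, groups)
        g1, _ = meta.select_candidates(
            comp, stats_df, groups, small_stats["library"], min_hairpins=1
        )
        g2, _ = meta.select_candidates(
            comp, stats_df, groups, small_stats["library"], min_hairpins=2
        )
        assert set(g2["gene_id"]) <= set(g1["gene_id"])

    def test_no_nontransformed_lines_warns_and_skips_clause(self, caplog):
        z, lfc, p, _, library = self._random_inputs(5)
        groups = {"I1": "IBC", "I2": "IBC", "N1": "nonIBC", "N2": "nonIBC",
                  "T1": "nonIBC"}
        stats_df = _stats_from_z(z, lfc=lfc, p=p)
        comp = meta.ibc_comparative(stats_df, groups)
        with caplog.at_level("WARNING"):
            meta.select_candidates(comp, stats_df, groups, library)
        assert any("exclusion clause skipped" in r.message for r in caplog.records)
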