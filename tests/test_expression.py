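"""Unit tests for expression normalization, bias calling and enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from neosexscan.expression import (
    ExpressionMatrix, call_biased_genes, chromosome_enrichment,
    cis_het_correlation, enrichment_windows, normalize_expression,
    presence_calls, read_expression, tissue_specific_genes,
)

from conftest import make_matrix


def _em(signals, tissues=None, sexes=None, species=None, chrom="c",
        probe_gene=None):
    arrays = list(signals.columns)
    n = len(arrays)
    array_map = pd.DataFrame({
        "array_id": arrays,
        "species": species or ["focal"] * n,
        "sex": sexes or ["male"] * n,
        "tissue": tissues or ["brain"] * n,
    })
    probes = list(signals.index)
    probe_map = pd.DataFrame({
        "probe_id": probes,
        "gene_id": probe_gene or [p.split("_")[0] for p in probes],
        "chrom": chrom, "tss": range(1, len(probes) + 1), "strand": "+",
    })
    return ExpressionMatrix(signals=signals, probe_map=probe_map,
                            array_map=array_map)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def test_percentile_linear_interpolation():
    # 75th percentile of {10,20,30,40} with linear interpolation is 32.5
    assert np.percentile([10, 20, 30, 40], 75) == pytest.approx(32.5)


def test_normalize_identical_probes_give_unit_values():
    """When every probe has the same signal on an array, the log-median
    division sends each stable probe's value to exactly 1."""
    sig = pd.DataFrame({"a1": [10.0, 20.0, 30.0, 40.0],
                        "a2": [100.0, 200.0, 300.0, 400.0]},
                       index=["g1_p1", "g2_p1", "g3_p1", "g4_p1"])
    em = normalize_expression(_em(sig))
    # per-array q75 scaling makes the two arrays identical; each probe's
    # median equals its value, so value/median = 1 everywhere
    assert np.allclose(em.signals.to_numpy(), 1.0)
    assert em.normalized
    assert em.n_floored == 0


def test_normalize_array_scale_invariance():
    rng = np.random.default_rng(4)
    base = rng.lognormal(3, 1, size=(50, 6))
    sig1 = pd.DataFrame(base, index=[f"g{i}_p1" for i in range(50)],
                        columns=[f"a{j}" for j in range(6)])
    scaled = base * np.array([1, 2, 0.5, 4, 1, 3])[None, :]
    sig2 = pd.DataFrame(scaled, index=sig1.index, columns=sig1.columns)
    n1 = normalize_expression(_em(sig1))
    n2 = normalize_expression(_em(sig2))
    assert np.allclose(n1.signals.to_numpy(), n2.signals.to_numpy())


def test_normalize_floors_and_counts():
    sig = pd.DataFrame({"a1": [0.0, 5.0, 10.0, 20.0],
                        "a2": [1.0, 5.0, 10.0, 20.0]},
                       index=[f"g{i}_p1" for i in range(4)])
    em = normalize_expression(_em(sig))
    assert em.n_floored == 1


def test_normalize_excludes_unstable_probes():
    rng = np.random.default_rng(5)
    vals = rng.lognormal(3, 1, size=(20, 5))
    sig = pd.DataFrame(vals, index=[f"g{i}_p1" for i in range(20)],
                       columns=[f"a{j}" for j in range(5)])
    # force one probe's log2 median to ~0 by pinning it at the q75 value
    # (iterated, since the pin itself moves the percentile slightly)
    for _ in range(50):
        x = np.maximum(sig.to_numpy(), 1e-6)
        q75 = np.percentile(x, 75, axis=0)
        sig.iloc[0] = q75
    em = normalize_expression(_em(sig))
    assert em.n_unstable_probes >= 1
    assert "g0_p1" not in em.signals.index


def test_normalize_twice_rejected():
    sig = pd.DataFrame({"a1": [1.0, 2.0], "a2": [3.0, 4.0]},
                       index=["g1_p1", "g2_p1"])
    em = normalize_expression(_em(sig))
    with pytest.raises(ValueError, match="already normalized"):
        normalize_expression(em)


def test_gene_values_average_probes():
    sig = pd.DataFrame({"a1": [1.0, 3.0, 10.0]},
                       index=["g1_p1", "g1_p2", "g2_p1"])
    em = _em(sig)
    gv = em.gene_values()
    assert gv.loc["g1", "a1"] == pytest.approx(2.0)
    assert gv.loc["g2", "a1"] == pytest.approx(10.0)


def test_read_expression_roundtrip(tmp_path):
    sig = pd.DataFrame({"a1": [1.0, 2.0], "a2": [3.0, 4.0]},
                       index=["g1_p1", "g2_p1"])
    em = _em(sig)
    em.signals.rename_axis("probe_id").to_csv(tmp_path / "s.tsv", sep="\t")
    em.probe_map.to_csv(tmp_path / "p.tsv", sep="\t", index=False)
    em.array_map.to_csv(tmp_path / "a.tsv", sep="\t", index=False)
    again = read_expression(tmp_path / "s.tsv", tmp_path / "p.tsv",
                            tmp_path / "a.tsv")
    assert np.allclose(again.signals.to_numpy(), sig.to_numpy())


# ---------------------------------------------------------------------------
# Bias calling
# ---------------------------------------------------------------------------

def _biased_em(n_genes=40, n_biased=8, effect=1.0, noise=0.2, seed=0):
    rng = np.random.default_rng(seed)
    males = [f"m{i}" for i in range(4)]
    females = [f"f{i}" for i in range(4)]
    arrays = males + females
    rows, index = [], []
    for g in range(n_genes):
        base = 8.0 + rng.normal(0, 2)
        shift = effect if g < n_biased else 0.0
        vals = [base + shift / 2 + rng.normal(0, noise) for _ in males] + \
               [base - shift / 2 + rng.normal(0, noise) for _ in females]
        rows.append(vals)
        index.append(f"g{g:03d}_p1")
    sig = pd.DataFrame(rows, index=index, columns=arrays)
    em = _em(sig, sexes=["male"] * 4 + ["female"] * 4)
    return em, males, females


def test_call_biased_genes_detects_planted_bias():
    em, males, females = _biased_em()
    calls = call_biased_genes(em, {"male": males, "female": females})
    flagged = set(calls.loc[calls["flagged"], "gene"])
    planted = {f"g{i:03d}" for i in range(8)}
    assert planted <= flagged
    for _, row in calls[calls["gene"].isin(planted)].iterrows():
        assert row["direction"] == "male"
        assert row["effect"] > 0


def test_call_biased_genes_null_fp_rate_near_alpha():
    n_flagged = total = 0
    for seed in range(5):
        em, males, females = _biased_em(n_genes=200, n_biased=0, seed=seed)
        calls = call_biased_genes(em, {"male": males, "female": females},
                                  alpha=0.05)
        n_flagged += int(calls["flagged"].sum())
        total += len(calls)
    rate = n_flagged / total
    se = math.sqrt(0.05 * 0.95 / total)
    assert abs(rate - 0.05) < 4 * se


def test_call_biased_genes_degenerate_and_validation():
    sig = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["g1_p1"],
                       columns=["m1", "m2", "f1", "f2"])
    em = _em(sig, sexes=["male", "male", "female", "female"])
    calls = call_biased_genes(em, {"male": ["m1", "m2"],
                                   "female": ["f1", "f2"]})
    assert calls.iloc[0]["direction"] == "degenerate"
    assert not calls.iloc[0]["flagged"]
    with pytest.raises(ValueError, match=">= 2 replicates"):
        call_biased_genes(em, {"male": ["m1"], "female": ["f1", "f2"]})
    with pytest.raises(ValueError, match="two groups"):
        call_biased_genes(em, {"male": ["m1", "m2"]})


# ---------------------------------------------------------------------------
# Presence and tissue specificity
# ---------------------------------------------------------------------------

def test_presence_and_tissue_specific():
    rng = np.random.default_rng(6)
    error = 4.0
    arrays = {"testis": [f"t{i}" for i in range(4)],
              "ovary": [f"o{i}" for i in range(4)],
              "brain": [f"b{i}" for i in range(4)]}
    cols = sum(arrays.values(), [])
    # g1: testis only; g2: everywhere; g3: nowhere
    def row(levels):
        return sum(([lv + rng.normal(0, 0.1) for _ in range(4)]
                    for lv in levels), [])
    sig = pd.DataFrame([row([9, 4, 4]), row([9, 9, 9]), row([4, 4, 4])],
                       index=["g1_p1", "g2_p1", "g3_p1"], columns=cols)
    em = _em(sig, tissues=["gonad"] * 8 + ["brain"] * 4,
             sexes=["male"] * 4 + ["female"] * 4 + ["male"] * 4)
    pres = presence_calls(em, arrays, error_log2=error)
    assert pres.loc["g1"].tolist() == [True, False, False]
    assert pres.loc["g2"].tolist() == [True, True, True]
    assert pres.loc["g3"].tolist() == [False, False, False]
    testis, ovary = tissue_specific_genes(pres)
    assert testis == {"g1"}
    assert ovary == set()


def test_tissue_specific_requires_columns():
    with pytest.raises(ValueError, match="missing column"):
        tissue_specific_genes(pd.DataFrame({"testis": [True]}))


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def _bias_frame(flags):
    return pd.DataFrame({"gene": [f"g{i}" for i in range(len(flags))],
                         "contrast": "sex", "effect": 0.0, "p": 0.5,
                         "direction": "male", "flagged": flags})


def test_chromosome_enrichment_detects_planted_excess(rng):
    chroms, flags = [], []
    genes_per = 100
    names = [f"a{i:02d}" for i in range(8)] + ["cand"]
    for c in names:
        p = 0.25 if c == "cand" else 0.05
        chroms += [c] * genes_per
        flags += (rng.random(genes_per) < p).tolist()
    calls = _bias_frame(flags)
    gene_chrom = pd.Series(chroms, index=calls["gene"])
    props, outliers = chromosome_enrichment(calls, gene_chrom, ["cand"],
                                            names[:-1])
    assert {o.label for o in outliers} == {"cand"}
    row = props.set_index("chrom").loc["cand"]
    assert row["n_genes"] == genes_per
    assert abs(row["proportion"] - 0.25) < 0.15


def test_chromosome_enrichment_min_genes_and_autosome_guard():
    calls = _bias_frame([True] * 10)
    gene_chrom = pd.Series(["tiny"] * 10, index=calls["gene"])
    with pytest.raises(ValueError, match=">= 4 autosomes"):
        chromosome_enrichment(calls, gene_chrom, ["tiny"], ["a1", "a2",
                                                            "a3", "a4"])


def test_enrichment_windows_proportions():
    calls = _bias_frame([True, False, True, False])
    gene_pos = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(4)], "chrom": "c",
        "tss": [100_000, 200_000, 1_500_000, 3_500_000], "strand": "+"})
    win = enrichment_windows(calls, gene_pos, "c", 4_000_000,
                             window=2_000_000, step=1_000_000)
    assert win.loc[0, "n_informative"] == 3
    assert win.loc[0, "value"] == pytest.approx(2 / 3)
    assert np.isnan(win.loc[2, "value"]) or win.loc[2, "n_informative"] >= 0


# ---------------------------------------------------------------------------
# Cis correlation
# ---------------------------------------------------------------------------

def test_cis_het_correlation_perfect_linear():
    """Genes whose upstream all-male-het site count increases linearly
    with their |sex effect| give r = 1."""
    n_genes = 6
    gene_info = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n_genes)], "chrom": "c",
        "tss": [100_000 * (i + 1) for i in range(n_genes)], "strand": "+"})
    chroms, positions, gts = [], [], []
    for i in range(n_genes):
        tss = 100_000 * (i + 1)
        for k in range(i):                     # i upstream het sites
            chroms.append("c")
            positions.append(tss - 1 - k)
            gts.append([1, 1, 0])              # het in both males, not female
    order = np.argsort(positions)
    m = make_matrix([chroms[i] for i in order],
                    [positions[i] for i in order],
                    np.asarray(gts, np.int8)[order], ["M1", "M2", "F1"])
    effect = pd.Series([0.1 * i for i in range(n_genes)],
                       index=gene_info["gene_id"])
    out = cis_het_correlation(effect, m, ["M1", "M2"], gene_info, "c")
    r, p = out["upstream_10kb"]
    assert r == pytest.approx(1.0)
    assert p < 0.01
    # sites sit within 6 bp of the TSS, so the 3 kb window sees them too
    assert out["upstream_3kb"][0] == pytest.approx(1.0)


def test_cis_het_correlation_degenerate_counts():
    gene_info = pd.DataFrame({
        "gene_id": ["g0", "g1", "g2"], "chrom": "c",
        "tss": [10_000, 20_000, 30_000], "strand": "+"})
    m = make_matrix(["c"], [1], np.asarray([[0, 0]], np.int8), ["M1", "M2"])
    effect = pd.Series([0.1, 0.2, 0.3], index=gene_info["gene_id"])
    out = cis_het_correlation(effect, m, ["M1", "M2"], gene_info, "c")
    assert math.isnan(out["upstream_10kb"][0])
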