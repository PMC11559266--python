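import numpy as np
import pytest

from sulfidogen import community as com
from sulfidogen import simulate as sim
from sulfidogen.community import (
    AbundanceTable,
    bray_curtis,
    bray_curtis_matrix,
    pcoa,
    rarefy,
    relative_abundance,
    shannon,
)


def _table(counts, groups=None):
    counts = np.atleast_2d(counts)
    return AbundanceTable(
        counts=counts,
        sample_ids=[f"s{i}" for i in range(counts.shape[0])],
        taxon_ids=[f"t{j}" for j in range(counts.shape[1])],
        groups=groups,
    )


def test_relative_abundance(rng):
    table = _table([[10, 10, 10, 10], [96, 4, 0, 0]])
    props = relative_abundance(table)
    np.testing.assert_allclose(props.iloc[0], 0.25)
    np.testing.assert_allclose(props.iloc[1], [0.96, 0.04, 0, 0])
    random = _table(rng.integers(1, 100, size=(6, 9)))
    np.testing.assert_allclose(relative_abundance(random).sum(axis=1), 1.0)


def test_relative_abundance_names_zero_sum_sample():
    with pytest.raises(ValueError, match="s1"):
        relative_abundance(_table([[1, 2], [0, 0]]))


def test_shannon_closed_forms():
    assert shannon([37]) == 0.0
    assert shannon([5, 5, 5, 5]) == pytest.approx(np.log(4))
    assert shannon([0.95, 0.05]) == pytest.approx(0.1985, abs=5e-4)
    assert shannon([1, 1, 1, 1], base=2) == pytest.approx(2.0)


def test_shannon_bounded_by_richness(rng):
    for _ in range(20):
        counts = rng.integers(0, 50, size=12)
        if counts.sum() == 0:
            continue
        S = int((counts > 0).sum())
        assert shannon(counts) <= np.log(max(S, 1)) + 1e-12


def test_shannon_matches_reference_oracle(rng):
    skbio_diversity = pytest.importorskip("skbio.diversity.alpha")
    for _ in range(10):
        counts = rng.integers(0, 200, size=15)
        counts[0] += 1
        ours = shannon(counts)
        ref = float(skbio_diversity.shannon(counts, base=np.e))
        assert ours == pytest.approx(ref, abs=1e-10)


def test_bray_curtis_examples():
    assert bray_curtis([6, 0, 2], [2, 2, 0]) == pytest.approx(8 / 12)
    assert bray_curtis([3, 1], [3, 1]) == 0.0
    assert bray_curtis([5, 0], [0, 7]) == 1.0
    with pytest.raises(ValueError):
        bray_curtis([1, 2], [1, 2, 3])


def test_bray_curtis_properties(rng):
    scipy_distance = pytest.importorskip("scipy.spatial.distance")
    for _ in range(20):
        x = rng.integers(0, 30, size=8).astype(float)
        y = rng.integers(0, 30, size=8).astype(float)
        if x.sum() == 0 or y.sum() == 0 or (x + y).sum() == 0:
            continue
        d = bray_curtis(x, y)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(bray_curtis(y, x))
        assert d == pytest.approx(float(scipy_distance.braycurtis(x, y)), abs=1e-12)
        perm = rng.permutation(8)
        assert bray_curtis(x[perm], y[perm]) == pytest.approx(d)
    assert bray_curtis([4, 4], [4, 4]) == 0.0


def test_pcoa_two_samples():
    res = pcoa([[0.0, 0.8], [0.8, 0.0]])
    coords = res.coordinates
    assert coords.shape == (2, 1)
    np.testing.assert_allclose(np.abs(coords[:, 0]), 0.4, atol=1e-12)
    assert coords[0, 0] == pytest.approx(-coords[1, 0])


def test_pcoa_equilateral_triangle():
    D = np.ones((3, 3)) - np.eye(3)
    res = pcoa(D)
    pos = res.eigenvalues[res.eigenvalues > 1e-12]
    assert len(pos) == 2
    assert pos[0] == pytest.approx(pos[1], abs=1e-10)
    C = res.coordinates
    for i in range(3):
        for j in range(i + 1, 3):
            assert np.linalg.norm(C[i] - C[j]) == pytest.approx(1.0, abs=1e-8)


def test_pcoa_euclidean_round_trip(rng):
    pts = rng.normal(size=(6, 3))
    D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    res = pcoa(D)
    C = res.coordinates
    D2 = np.linalg.norm(C[:, None, :] - C[None, :, :], axis=-1)
    np.testing.assert_allclose(D2, D, atol=1e-8)
    assert np.all(np.diff(res.eigenvalues) <= 1e-10)  # descending order


def test_pcoa_matches_reference_oracle(rng):
    skbio_ord = pytest.importorskip("skbio.stats.ordination")
    from skbio import DistanceMatrix

    counts = rng.integers(1, 60, size=(5, 10)).astype(float)
    D = bray_curtis_matrix(_table(counts))
    ours = pcoa(D)
    ref = skbio_ord.pcoa(DistanceMatrix(D), method="eigh")
    ref_eigs = np.asarray(ref.eigvals)
    np.testing.assert_allclose(
        ours.eigenvalues[: len(ref_eigs)], ref_eigs, atol=1e-8
    )
    k = (ours.eigenvalues > 1e-12).sum()
    ref_coords = np.asarray(ref.samples)[:, :k]
    # eigenvectors match up to sign per axis
    for ax in range(k):
        col, ref_col = ours.coordinates[:, ax], ref_coords[:, ax]
        assert min(
            np.abs(col - ref_col).max(), np.abs(col + ref_col).max()
        ) < 1e-8


def test_pcoa_rejects_bad_input():
    with pytest.raises(ValueError):
        pcoa([[0, 1], [2, 0]])
    with pytest.raises(ValueError):
        pcoa([[1.0]])


def test_planted_dominance_lowers_shannon():
    wins = 0
    for seed in range(50):
        table = sim.generate_community_table(n_samples=2, depth=5000, seed=seed)
        by_group = {}
        for g, row in zip(table.groups, table.counts):
            by_group.setdefault(g, []).append(shannon(row))
        if np.mean(by_group["Gly+S"]) < np.mean(by_group["S0"]):
            wins += 1
    assert wins >= 48  # >= 95% of seeds


def test_pcoa_separates_planted_groups():
    from sklearn.metrics import silhouette_score

    scores = []
    for seed in range(10):
        table = sim.generate_community_table(n_samples=3, depth=5000, seed=seed)
        res = pcoa(bray_curtis_matrix(table))
        scores.append(silhouette_score(res.coordinates[:, :2], table.groups))
    assert np.mean(scores) > 0


def test_rarefy_depth_and_determinism():
    table = _table([[100, 50, 25], [10, 10, 10]])
    sub = rarefy(table, depth=30, seed=1)
    np.testing.assert_allclose(sub.counts.sum(axis=1), 30)
    assert np.all(sub.counts <= table.counts)
    sub2 = rarefy(table, depth=30, seed=1)
    np.testing.assert_array_equal(sub.counts, sub2.counts)
    with pytest.raises(ValueError):
        rarefy(table, depth=31, seed=1)


def test_tsv_round_trip(tmp_path):
    table = sim.generate_community_table(n_samples=2, depth=1000, seed=3)
    path = tmp_path / "table.tsv"
    table.write_tsv(path)
    back = AbundanceTable.read_tsv(path)
    np.testing.assert_array_equal(back.counts, table.counts)
    assert back.groups == table.groups
    assert back.taxon_ids == table.taxon_ids
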