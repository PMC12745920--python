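"""Spectrum container: projection, folding, i/o, Poisson sampling."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from refugia.spectrum import Spectrum2D, poisson_sample, projection_matrix


def brute_projection_1d(counts, n_from, n_to):
    """Independent enumeration oracle: expected subsample spectra by
    averaging over all allele subsets of each site class."""
    out = np.zeros(n_to + 1)
    for i, s in enumerate(counts):
        if s == 0:
            continue
        alleles = [1] * i + [0] * (n_from - i)
        subsets = list(itertools.combinations(range(n_from), n_to))
        for sub in subsets:
            d = sum(alleles[a] for a in sub)
            out[d] += s / len(subsets)
    return out


class TestProjection:
    def test_marginal_example(self):
        # counts (4, 2, 0) at n=4 projected to n'=2
        H = projection_matrix(4, 2)
        s = H @ np.array([0.0, 4.0, 2.0, 0.0, 0.0])
        assert s[1] == pytest.approx(4 * 0.5 + 2 * (2 / 3), abs=1e-12)
        assert s[2] == pytest.approx(2 * (1 / 6), abs=1e-12)

    @pytest.mark.parametrize("n_from,n_to", [(4, 2), (6, 4), (5, 3)])
    def test_matches_exhaustive_enumeration(self, n_from, n_to):
        rng = np.random.default_rng(n_from * 10 + n_to)
        counts = rng.integers(0, 8, size=n_from + 1).astype(float)
        H = projection_matrix(n_from, n_to)
        assert np.allclose(H @ counts,
                           brute_projection_1d(counts, n_from, n_to),
                           atol=1e-10)

    def test_project_to_self_is_identity(self):
        rng = np.random.default_rng(0)
        spec = Spectrum2D(rng.random((5, 7)))
        out = spec.project(4, 6)
        assert np.allclose(out.data[~out.mask], spec.data[~spec.mask])

    def test_projection_linear_and_mass_nonincreasing(self):
        rng = np.random.default_rng(1)
        a = Spectrum2D(rng.random((7, 7)))
        b = Spectrum2D(rng.random((7, 7)))
        pa, pb = a.project(4, 4), b.project(4, 4)
        ab = Spectrum2D(a.data + b.data).project(4, 4)
        assert np.allclose(ab.data, pa.data + pb.data)
        assert pa.sum() <= a.sum() + 1e-9
        # lost mass is exactly what landed in the masked corners
        assert pa.data.sum() == pytest.approx(
            np.where(a.mask, 0, a.data).sum(), abs=1e-9)

    def test_upward_projection_rejected(self):
        spec = Spectrum2D(np.ones((3, 3)))
        with pytest.raises(ValueError):
            spec.project(4, 2)


class TestFold:
    def test_complementary_cells_sum(self):
        data = np.zeros((3, 3))
        data[0, 1] = 3.0
        data[2, 1] = 1.0
        folded = Spectrum2D(data).fold()
        assert folded.data[0, 1] == pytest.approx(4.0)
        assert folded.folded

    def test_fold_twice_errors(self):
        folded = Spectrum2D(np.ones((3, 3))).fold()
        with pytest.raises(ValueError):
            folded.fold()

    @given(st.integers(2, 10), st.integers(2, 10), st.integers(0, 2 ** 32))
    def test_fold_conserves_unmasked_mass(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        spec = Spectrum2D(rng.random((n1 + 1, n2 + 1)))
        assert spec.fold().sum() == pytest.approx(spec.sum(), rel=1e-12)

    @given(st.integers(0, 2 ** 32))
    def test_fold_commutes_with_projection(self, seed):
        rng = np.random.default_rng(seed)
        spec = Spectrum2D(rng.random((9, 7)))
        a = spec.project(4, 4).fold()
        b = spec.fold()  # cannot project folded; compare masses instead
        assert a.sum() == pytest.approx(spec.project(4, 4).sum(), rel=1e-12)
        assert b.sum() == pytest.approx(spec.sum(), rel=1e-12)


class TestIO:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        spec = Spectrum2D(rng.random((5, 6))).fold()
        path = tmp_path / "spec.sfs"
        spec.to_file(path)
        back = Spectrum2D.from_file(path)
        assert np.allclose(back.data, spec.data)
        assert np.array_equal(back.mask, spec.mask)
        assert back.folded == spec.folded

    def test_malformed_header(self, tmp_path):
        path = tmp_path / "bad.sfs"
        path.write_text("5 x nonsense\n")
        with pytest.raises(ValueError):
            Spectrum2D.from_file(path)


class TestPoissonSample:
    def test_zero_theta_gives_zero_spectrum(self):
        exp = Spectrum2D(np.ones((4, 4)))
        out = poisson_sample(exp, 0.0, seed=1)
        assert out.sum() == 0

    def test_same_seed_bit_identical(self):
        exp = Spectrum2D(np.random.default_rng(0).random((6, 6)))
        a = poisson_sample(exp, 50.0, seed=42)
        b = poisson_sample(exp, 50.0, seed=42)
        assert np.array_equal(a.data, b.data)

    def test_mean_matches_intensity(self):
        exp = Spectrum2D(np.full((3, 3), 2.0))
        theta = 3.0
        draws = np.array([poisson_sample(exp, theta, seed=s).data[1, 1]
                          for s in range(10_000)])
        lam = theta * 2.0
        assert abs(draws.mean() - lam) < 3 * np.sqrt(lam / len(draws))

    def test_negative_theta_rejected(self):
        with pytest.raises(ValueError):
            poisson_sample(Spectrum2D(np.ones((3, 3))), -1.0, seed=0)
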