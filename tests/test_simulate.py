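import numpy as np
import pytest
from scipy.stats import pearsonr, spearmanr

from traitwebs.clustering import agglomerate, cut_clusters
from traitwebs.data import write_interactions, write_specimens
from traitwebs.regression import fit_bee_model, predict_traits
from traitwebs.simulate import SimParams, paper_shaped_preset, simulate_community


def small_params(**overrides):
    defaults = dict(
        n_plant_species=3,
        n_bee_species=4,
        plant_fds_mean=(10.0, 20.0, 30.0),
        plant_fds_sd=(1.0, 2.0, 3.0),
        bee_itd_mean=(2.0, 3.0, 4.0, 5.0),
        bee_itd_sd=(0.2, 0.2, 0.2, 0.2),
        sigma_match=1.0,
        lam=0.5,
        n_interactions=60,
        floor_species=("Plant_01",),
        seed=1,
    )
    defaults.update(overrides)
    return SimParams(**defaults)


class TestSimParams:
    def test_validation(self):
        with pytest.raises(ValueError, match="lam"):
            small_params(lam=1.5)
        with pytest.raises(ValueError, match="n_interactions"):
            small_params(n_interactions=0)
        with pytest.raises(ValueError, match="plant_fds_mean"):
            small_params(plant_fds_mean=(10.0,))

    def test_species_names(self):
        p = small_params()
        assert p.plant_species_names[0] == "Plant_01"
        assert p.bee_species_names[-1] == "Bee_04"


class TestSimulateCommunity:
    def test_shapes_and_reproducibility(self, tmp_path):
        ds1 = simulate_community(small_params())
        ds2 = simulate_community(small_params())
        assert len(ds1.interactions) == 60
        # byte-identical serialized tables for the same seed
        for name, ds in (("a", ds1), ("b", ds2)):
            write_interactions(ds.interactions, tmp_path / f"{name}_i.csv")
            write_specimens(ds.specimens, tmp_path / f"{name}_s.csv")
        assert (tmp_path / "a_i.csv").read_bytes() == (tmp_path / "b_i.csv").read_bytes()
        assert (tmp_path / "a_s.csv").read_bytes() == (tmp_path / "b_s.csv").read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_community(small_params(seed=1))
        b = simulate_community(small_params(seed=2))
        assert a.interactions != b.interactions

    def test_floor_species_have_no_specimens(self):
        ds = simulate_community(small_params())
        assert all(s.species != "Plant_01" for s in ds.specimens if s.side == "plant")
        assert ds.immeasurable_plant_species == {"Plant_01"}

    def test_lambda_zero_no_trait_matching(self):
        # random mixing: predicted PL and NHD uncorrelated across records
        ds = simulate_community(small_params(lam=0.0, n_interactions=400, seed=3))
        predicted = predict_traits(ds)
        ids = [r.record_id for r in ds.interactions]
        r = pearsonr(
            [predicted.proboscis_mm[i] for i in ids],
            [predicted.nhd_mm[i] for i in ids],
        ).statistic
        assert abs(r) < 0.15

    def test_strong_kernel_forces_matching(self):
        # lam=1, sigma=0.3, well-spread traits -> Spearman(PL, NHD) > 0.5
        params = small_params(
            lam=1.0,
            sigma_match=0.3,
            n_interactions=300,
            bee_itd_mean=(1.5, 3.0, 4.5, 6.0),
            bee_itd_sd=(0.1,) * 4,
            floor_species=(),
            plant_fds_mean=(10.0, 25.0, 40.0),
            plant_fds_sd=(1.0, 1.0, 1.0),
            seed=4,
        )
        ds = simulate_community(params)
        predicted = predict_traits(ds)
        ids = [r.record_id for r in ds.interactions]
        rho = spearmanr(
            [predicted.proboscis_mm[i] for i in ids],
            [predicted.nhd_mm[i] for i in ids],
        ).statistic
        assert rho > 0.5

    def test_infeasible_kernel_errors(self):
        with pytest.raises(RuntimeError, match="infeasible"):
            simulate_community(small_params(lam=1.0, sigma_match=0.0, seed=5))


class TestParameterRecovery:
    def test_bee_link_recovered_within_3se(self):
        slope, intercept, noise = 1.4, 0.1, 0.15
        misses = 0
        for rep in range(60):
            params = small_params(
                seed=100 + rep,
                bee_link=(slope, intercept, noise),
                n_specimens_per_species=13,  # 4 species -> n = 52 points
            )
            ds = simulate_community(params)
            model = fit_bee_model(ds.specimens)
            x = np.array([s.predictor_mm for s in ds.specimens if s.side == "bee"])
            se = noise / np.sqrt(np.sum((x - x.mean()) ** 2))
            misses += abs(model.slope - slope) > 3 * se
        assert misses <= 5


class TestClusterRecovery:
    def test_well_separated_species_recovered_exactly(self):
        params = small_params(
            bee_itd_mean=(1.0, 4.0, 7.0, 10.0),
            bee_itd_sd=(0.05,) * 4,
            lam=0.0,
            n_interactions=120,
            seed=6,
        )
        ds = simulate_community(params)
        ids = [r.record_id for r in ds.interactions]
        species = [r.bee_species for r in ds.interactions]
        tree = agglomerate([r.itd_mm for r in ds.interactions])
        nodes = cut_clusters(tree, len(set(species)), ids, species, "bee")
        # each node contains exactly one species and vice versa
        for summary in nodes.nodes.values():
            assert len(summary.species) == 1
        assert len({next(iter(s.species)) for s in nodes.nodes.values()}) == len(
            set(species)
        )


class TestPreset:
    def test_shape(self):
        p = paper_shaped_preset()
        assert p.n_plant_species == 10
        assert p.n_bee_species == 28
        assert len(p.floor_species) == 4
        assert p.n_interactions == 272

    @pytest.mark.parametrize("seed", [0, 7, 23])
    def test_nhd_within_bounds(self, seed):
        ds = simulate_community(paper_shaped_preset(seed=seed))
        predicted = predict_traits(ds)
        nhd = np.array(list(predicted.nhd_mm.values()))
        assert nhd.min() >= 1.0 - 1e-9
        # regression predictions track the clipped generative range loosely
        assert nhd.max() <= 11.0

    def test_preset_deterministic(self):
        a = simulate_community(paper_shaped_preset(seed=5))
        b = simulate_community(paper_shaped_preset(seed=5))
        assert a.interactions == b.interactions


class TestStructureCalibration:
    def test_matching_kernel_shapes_network(self):
        """The size-matching kernel measurably restructures the trait network.

        Random mixing (lam = 0) yields margin-proportional tables, which are
        close to maximally nested; pure size matching (lam = 1) superimposes
        a band structure that lowers weighted nestedness.  The kernel's
        effect is asserted as a consistent separation between the two.
        """
        from traitwebs.build import build_trait_network
        from traitwebs.metrics import wnodf

        lower = 0
        n_rep = 10
        for seed in range(n_rep):
            values = {}
            for lam in (0.0, 1.0):
                ds = simulate_community(paper_shaped_preset(seed=seed, lam=lam))
                predicted = predict_traits(ds)
                ids = [r.record_id for r in ds.interactions]
                nhd = [predicted.nhd_mm[i] for i in ids]
                itd = [predicted.itd_mm[i] for i in ids]
                pn = cut_clusters(
                    agglomerate(nhd), 6, ids, [r.plant_species for r in ds.interactions], "plant"
                )
                bn = cut_clusters(
                    agglomerate(itd), 5, ids, [r.bee_species for r in ds.interactions], "bee"
                )
                values[lam] = wnodf(build_trait_network(ds.interactions, pn, bn).matrix)
            lower += values[1.0] < values[0.0]
        assert lower >= 9
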