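"""Synthetic survey generator: determinism, calibration and moments."""

import numpy as np
import pytest

from seedbank import (
    MODES,
    SimulationDesign,
    ValidationError,
    counts_to_density,
    generate_dataset,
    generate_practices,
    generate_survey,
    guild_composition,
    phytosociology_table,
    species_pool,
    survey_frame,
)


class TestPractices:
    def test_mode_typical_contrasts(self):
        practices = generate_practices(SimulationDesign(sites_per_mode=5), rng=0)
        mean = lambda mode, attr: np.mean(
            [getattr(p, attr) for p in practices if p.mode == mode]
        )
        # monoculture relies on roughly twice the organic fertilizer
        assert mean("RM", "organic_fertilizer_1e3kg_ha") > 1.5 * mean(
            "RG", "organic_fertilizer_1e3kg_ha"
        )
        # coculture modes irrigate more and hand-weed about half as much
        for mode in ("RC", "RD"):
            assert mean(mode, "irrigation_1e3m3_ha") > mean("RG", "irrigation_1e3m3_ha")
            assert mean(mode, "hand_weeding_h_ha") < 0.7 * mean("RG", "hand_weeding_h_ha")

    def test_empty_design(self):
        assert generate_practices(SimulationDesign(sites_per_mode=0), rng=0) == []

    def test_years_in_range(self):
        practices = generate_practices(SimulationDesign(sites_per_mode=20), rng=1)
        assert all(3 <= p.consecutive_years <= 10 for p in practices)

    def test_invalid_design_rejected(self):
        design = SimulationDesign(mode_guild_profile={m: (0.5, 0.5, 0.5) for m in MODES})
        with pytest.raises(ValidationError):
            generate_practices(design, rng=0)


class TestSurvey:
    def test_fixed_seed_reproducible(self):
        design = SimulationDesign(rng_seed=42)
        q1, p1, _ = generate_dataset(design)
        q2, p2, _ = generate_dataset(design)
        assert survey_frame(q1).equals(survey_frame(q2))
        assert p1 == p2

    def test_counts_are_non_negative_integers(self, small_dataset):
        _, quadrats, _, _ = small_dataset
        for q in quadrats:
            assert all(isinstance(n, int) and n >= 0 for n in q.counts.values())

    def test_design_cardinality(self, small_dataset):
        design, quadrats, practices, _ = small_dataset
        assert len(practices) == 4 * design.sites_per_mode
        assert len(quadrats) == len(practices) * design.fields_per_site * design.quadrats_per_field

    def test_mean_density_recovered(self):
        """With site density noise off, the empirical mean total density
        matches the design constant within 5% over ≥10⁴ quadrats."""
        design = SimulationDesign(
            sites_per_mode=24, quadrats_per_field=40, density_site_sd=0.0, rng_seed=7
        )
        quadrats, _, _ = generate_dataset(design)
        assert len(quadrats) >= 10_000
        mean_density = np.mean(
            [sum(counts_to_density(q).values()) for q in quadrats]
        )
        assert mean_density == pytest.approx(design.mean_total_density, rel=0.05)

    def test_poisson_limit_variance_equals_mean(self):
        """overdispersion_k → ∞ (None) degenerates to Poisson: per-species
        count variance ≈ mean, estimated over ≥10⁴ draws."""
        design = SimulationDesign(
            sites_per_mode=1,
            fields_per_site=1,
            quadrats_per_field=12000,
            overdispersion_k=None,
            site_sd=0.0,
            field_sd=0.0,
            density_site_sd=0.0,
            covariate_effect={},
            rng_seed=3,
        )
        quadrats, _, truth = generate_dataset(design)
        label = next(iter(truth.species_abundance))
        site = label.split("/")[0]
        rel = truth.species_abundance[label]
        sp = truth.species_ids[int(np.argmax(rel))]  # most abundant species
        counts = np.array(
            [q.counts.get(sp, 0) for q in quadrats if q.site_id == site]
        )
        assert len(counts) == 12000
        assert counts.var() == pytest.approx(counts.mean(), rel=0.05)

    def test_overdispersed_counts_exceed_poisson_variance(self):
        design = SimulationDesign(
            sites_per_mode=1,
            fields_per_site=1,
            quadrats_per_field=4000,
            overdispersion_k=1.0,
            site_sd=0.0,
            field_sd=0.0,
            density_site_sd=0.0,
            covariate_effect={},
            rng_seed=3,
        )
        quadrats, _, truth = generate_dataset(design)
        label = next(iter(truth.species_abundance))
        sp = truth.species_ids[int(np.argmax(truth.species_abundance[label]))]
        counts = np.array([q.counts.get(sp, 0) for q in quadrats])
        # NB variance = μ + μ²/k ≫ μ for abundant species
        assert counts.var() > 2 * counts.mean()

    def test_equal_profile_no_effects_gives_equal_guild_shares(self):
        """Full symmetry (equal guild shares AND equal per-guild pool
        sizes) gives guild IV shares near 1/3 each; unequal pool sizes
        would legitimately tilt the frequency term of IV."""
        design = SimulationDesign(
            sites_per_mode=12,
            species_per_guild=(15, 15, 15),
            mode_guild_profile={m: (1 / 3, 1 / 3, 1 / 3) for m in MODES},
            covariate_effect={},
            site_sd=0.0,
            field_sd=0.0,
            rng_seed=11,
        )
        quadrats, _, _ = generate_dataset(design)
        pool = species_pool(design)
        guild_map = {s.species_id: s.guild for s in pool}
        comp = guild_composition(phytosociology_table(quadrats), guild_map)
        assert np.allclose(comp.to_numpy(), 100 / 3, atol=6.0)

    def test_modal_guild_follows_mode_profile(self):
        """With the dominant-guild share at 0.47 for the duck-coculture
        profile and a balanced pool, grass is the modal guild of RD fields."""
        design = SimulationDesign(
            sites_per_mode=6,
            species_per_guild=(12, 12, 12),
            covariate_effect={},
            rng_seed=13,
        )
        quadrats, _, _ = generate_dataset(design)
        guild_map = {s.species_id: s.guild for s in species_pool(design)}
        rd = [q for q in quadrats if q.mode == "RD"]
        comp = guild_composition(phytosociology_table(rd), guild_map)
        assert comp.idxmax() == "grass"

    def test_missing_practices_rejected(self):
        design = SimulationDesign(rng_seed=0)
        practices = generate_practices(design, rng=0)
        quadrats_design = SimulationDesign(sites_per_mode=0, rng_seed=0)
        # survey generation iterates the given practices; an empty table
        # with a non-empty design is a coverage mismatch at the ABT stage,
        # while an invalid design fails upfront
        with pytest.raises(ValidationError):
            generate_survey(SimulationDesign(fields_per_site=0), practices, rng=0)

    def test_synthetic_pool_sizes(self):
        design = SimulationDesign(species_per_guild=(4, 3, 2))
        pool = species_pool(design)
        assert len(pool) == 9
        assert sum(s.guild == "grass" for s in pool) == 4
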