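import numpy as np
import pandas as pd
import pytest

from plumagescore import (
    PlumageImage,
    TaxonomySpec,
    build_histogram,
    generate_plumage_image,
    generate_taxonomy,
    quantify_image,
    representative_colors,
    rgb_to_lab,
    simulate_attractiveness,
    simulate_ratings,
)
from plumagescore.categories import CATEGORIES

from conftest import brute_force_bin


# -- taxonomy ---------------------------------------------------------------

def test_minimal_taxonomy_is_one_row():
    spec = TaxonomySpec(n_orders=1, families_per_order=1, genera_per_family=1,
                        species_per_genus=1, dichromatic_fraction=0.0, seed=1)
    tax = generate_taxonomy(spec)
    assert len(tax) == 1
    assert tax.iloc[0]["sex"] == "undefined"


def test_fully_dichromatic_taxonomy_doubles_rows():
    spec = TaxonomySpec(n_orders=2, families_per_order=2, genera_per_family=2,
                        species_per_genus=2, dichromatic_fraction=1.0, seed=1)
    tax = generate_taxonomy(spec)
    assert len(tax) == 32  # 16 species x 2 sexes
    assert set(tax["sex"]) == {"male", "female"}
    assert tax["species_id"].nunique() == 16


def test_taxonomy_path_is_unique_per_species():
    tax = generate_taxonomy(TaxonomySpec(n_orders=3, families_per_order=(1, 3),
                                         genera_per_family=(1, 3), species_per_genus=(1, 4),
                                         dichromatic_fraction=0.5, seed=11))
    paths = tax.groupby("species_id")[["order", "family", "genus"]].nunique()
    assert (paths == 1).all().all()
    # dichromatic species have exactly male+female rows, monomorphic one row
    by_sp = tax.groupby("species_id")["sex"].apply(set)
    for sexes in by_sp:
        assert sexes in ({"undefined"}, {"male", "female"})


def test_taxonomy_deterministic_for_fixed_seed():
    spec = TaxonomySpec(n_orders=2, families_per_order=(1, 2), genera_per_family=(1, 2),
                        species_per_genus=(1, 3), dichromatic_fraction=0.4, seed=99)
    assert generate_taxonomy(spec).equals(generate_taxonomy(spec))


def test_invalid_taxonomy_spec_rejected():
    with pytest.raises(ValueError):
        TaxonomySpec(n_orders=0)
    with pytest.raises(ValueError):
        TaxonomySpec(species_per_genus=(3, 1))


# -- plumage images ---------------------------------------------------------

def test_pure_blue_image_maps_entirely_to_blue(grid, cmap):
    image, hist = generate_plumage_image({"blue": 1.0}, size=16, seed=0, grid=grid)
    assert hist.n_occupied == 1
    assert cmap.category_of(tuple(hist.cells[0])) == "blue"
    assert hist.n_pixels == image.n_foreground


def test_half_red_half_black_pixel_split(grid):
    image, hist = generate_plumage_image({"red": 0.5, "black": 0.5},
                                         size=(102, 102), seed=3, grid=grid)
    assert image.n_foreground == 10_000
    assert sorted(hist.counts) == [5000, 5000]


@pytest.mark.parametrize("layout", ["stripe", "blob"])
def test_expected_histogram_equals_bruteforce_rebinning(grid, layout, rng):
    mix = {"blue": 0.4, "brown": 0.3, "white": 0.2, "red": 0.1}
    image, expected = generate_plumage_image(mix, layout=layout, size=24,
                                             seed=7, grid=grid, colors_per_category=2)
    lab = rgb_to_lab(image)
    oracle = brute_force_bin(lab, grid)
    assert expected.as_dict().keys() == oracle.keys()
    for cell, count in zip(expected.cells, expected.counts):
        assert oracle[tuple(cell)] == count


def test_mix_counts_within_one_pixel_of_rounding(grid, cmap):
    mix = {"green": 1 / 3, "grey": 1 / 3, "yellow": 1 / 3}
    image, hist = generate_plumage_image(mix, size=32, seed=5, grid=grid)
    n_fg = image.n_foreground
    by_cat: dict[str, int] = {}
    for cell, count in zip(hist.cells, hist.counts):
        cat = cmap.category_of(tuple(cell))
        by_cat[cat] = by_cat.get(cat, 0) + int(count)
    for cat, share in mix.items():
        assert abs(by_cat[cat] - share * n_fg) <= 1.0


def test_image_generator_rejects_bad_mixes():
    with pytest.raises(ValueError):
        generate_plumage_image({}, seed=0)
    with pytest.raises(ValueError, match="unknown"):
        generate_plumage_image({"octarine": 1.0}, seed=0)
    with pytest.raises(ValueError, match="simplex"):
        generate_plumage_image({"blue": 0.7}, seed=0)


def test_image_round_trips_through_png(tmp_path, grid):
    image, hist = generate_plumage_image({"rufous": 0.6, "black": 0.4}, size=20,
                                         seed=9, grid=grid, species_id="sp1", sex="male")
    path = tmp_path / "sp1_male.png"
    image.save_png(path)
    again = PlumageImage.load(path, species_id="sp1", sex="male")
    assert np.array_equal(again.rgb, image.rgb)
    assert np.array_equal(again.mask, image.mask)
    hist2 = quantify_image(again, grid)
    assert np.array_equal(hist.cells, hist2.cells)
    assert np.array_equal(hist.counts, hist2.counts)


def test_representative_colors_land_in_their_category(grid, cmap):
    reps = representative_colors(grid, n_per_category=3)
    assert set(reps) == set(CATEGORIES)
    for cat, colors in reps.items():
        for rgb in colors:
            lab = rgb_to_lab(np.array([rgb], dtype=np.uint8))
            cell, _ = grid.cell_index(lab)
            assert cmap.category_of(tuple(cell[0])) == cat


# -- attractiveness simulation ---------------------------------------------

def _flat_traits(n, rng):
    return pd.DataFrame({
        "species_id": [f"s{i}" for i in range(n)],
        "x1": rng.normal(size=n),
    })


def test_null_model_centres_on_half(rng):
    traits = _flat_traits(10_000, rng)
    truth = simulate_attractiveness(traits, coefficients={}, sigmas={}, phi=30.0, seed=4)
    y = truth.frame["response"]
    assert abs(y.mean() - 0.5) < 0.01
    assert ((y > 0) & (y < 1)).all()


def test_positive_coefficient_gives_positive_correlation(rng):
    traits = _flat_traits(2000, rng)
    truth = simulate_attractiveness(traits, coefficients={"x1": 1.0}, phi=30.0, seed=4)
    assert np.corrcoef(traits["x1"], truth.frame["response"])[0, 1] > 0.5


def test_simulation_matches_independent_rescript():
    """Re-derive the exact draws with a separately scripted generator."""
    rng = np.random.default_rng(0)
    traits = pd.DataFrame({
        "order": np.repeat(["o1", "o2"], 250),
        "x1": rng.normal(size=500),
    })
    truth = simulate_attractiveness(traits, coefficients={"x1": 0.5},
                                    sigmas={"order": 0.3}, phi=20.0, seed=77,
                                    intercept=0.2)
    # independent re-simulation following the documented draw order
    rng2 = np.random.default_rng(np.random.SeedSequence(77).spawn(5)[4])
    b = rng2.normal(0.0, 0.3, 2)  # levels sorted: o1, o2
    eta = 0.2 + 0.5 * traits["x1"].to_numpy() + np.where(traits["order"] == "o1", b[0], b[1])
    mu = np.clip(1 / (1 + np.exp(-eta)), 1e-6, 1 - 1e-6)
    y = np.clip(rng2.beta(mu * 20.0, (1 - mu) * 20.0), 1e-10, 1 - 1e-10)
    assert np.array_equal(truth.frame["response"].to_numpy(), y)


def test_simulation_validates_inputs(rng):
    traits = _flat_traits(10, rng)
    with pytest.raises(ValueError):
        simulate_attractiveness(traits, {}, sigmas={"species_id": -1.0})
    with pytest.raises(ValueError):
        simulate_attractiveness(traits, {}, phi=0.0)


# -- ratings ----------------------------------------------------------------

def _truth_frame(n, rng):
    return pd.DataFrame({
        "species_id": [f"s{i}" for i in range(n)],
        "sex": "undefined",
        "response": rng.uniform(0.1, 0.9, n),
    })


def test_zero_noise_ratings_are_monotone_in_truth(rng):
    truth = _truth_frame(40, rng).sort_values("response")
    sim = simulate_ratings(truth, n_raters=10, ratings_per_photo=2, quality_effect=0.0,
                           language_effects={"en": 0.0}, photo_sd=0.0, noise_sd=0.0, seed=6)
    mean_by_sp = sim.ratings.groupby("species_id")["rating"].mean()
    ordered = mean_by_sp.loc[truth["species_id"]].to_numpy()
    assert (np.diff(ordered) >= 0).all()
    expect = np.clip(np.round(1 + 9 * truth["response"].to_numpy()), 1, 10)
    assert np.array_equal(sim.ratings.groupby("species_id")["rating"].first().loc[truth["species_id"]].to_numpy(), expect)


def test_photo_counts_average_near_five(rng):
    truth = _truth_frame(400, rng)
    sim = simulate_ratings(truth, n_raters=20, ratings_per_photo=1, seed=8)
    per_species = sim.photos.groupby("species_id").size()
    assert per_species.between(1, 15).all()
    assert abs(per_species.mean() - 5.0) < 0.3


def test_ratings_in_scale_and_groupby_oracle(rng):
    truth = _truth_frame(30, rng)
    sim = simulate_ratings(truth, n_raters=25, ratings_per_photo=4, quality_effect=0.2,
                           language_effects={"en": 0.0, "fi": 0.4}, photo_sd=0.2,
                           noise_sd=1.0, seed=13)
    r = sim.ratings
    assert r["rating"].between(1, 10).all()
    assert r["photo_quality"].between(1, 5).all()
    # per-photo means recomputed independently
    means = {}
    counts = {}
    for row in r.itertuples():
        means[row.photo_id] = means.get(row.photo_id, 0.0) + row.rating
        counts[row.photo_id] = counts.get(row.photo_id, 0) + 1
    expected = {k: means[k] / counts[k] for k in means}
    got = r.groupby("photo_id")["rating"].mean().to_dict()
    assert got == pytest.approx(expected)


def test_ratings_validate_inputs(rng):
    truth = _truth_frame(5, rng)
    with pytest.raises(ValueError):
        simulate_ratings(truth, n_raters=0)
    with pytest.raises(ValueError):
        simulate_ratings(truth, photo_range=(0, 5))
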