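# Bundled toy scenario: ~50 species end-to-end in well under two minutes.
seed: 42
output_dir: plumagescore_out
scenario:
  taxonomy:
    n_orders: 4
    families_per_order: 2
    genera_per_family: 2
    species_per_genus: [2, 4]
    dichromatic_fraction: 0.3
  image:
    size: 24
    layout: stripe
    colors_per_category: 2
  attractiveness:
    phi: 30.0
    intercept: 0.0
  ratings:
    n_raters: 60
    mean_photos: 5.0
    ratings_per_photo: 5
    quality_effect: 0.15
    photo_sd: 0.3
    noise_sd: 1.0
    language_effects: {en: 0.0, fi: 0.2, es: -0.2}
grid: {a_bins: 12, b_bins: 12, L_bins: 4}
models: [main]
collinearity_threshold: 0.6
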