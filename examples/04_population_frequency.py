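"""Genic H3K9me3 versus nearest-TE population frequency.

Runs the full pipeline — genome, density tracks, piRNA reads, population
panel — then builds per-gene records and estimates the headline
associations: if heterochromatin spreading is deleterious, TEs near
high-H3K9me3 genes should segregate at lower population frequencies.
"""
import tespread as ts

cfg = ts.SynthConfig(seed=11)
ds = ts.simulate_dataset(cfg)
tracks = [ts.clamp_track(t) for t in ds.tracks]
weighted = ts.assign_mapping_weights(ds.reads)
records = ts.build_gene_records(
    ds.annotation, tracks, weighted, ds.te_frequency, ds.recomb_map
)

stage = cfg.stages[0]
a = ts.headline_associations(records, stage)
print(f"{a['n_pairs']} gene-TE pairs with a unique nearest TE ({stage})")
print(f"rho(H3K9me3, distance)        = {a['rho_distance']:+.3f}  (p {a['p_distance']:.2g})")
print(f"rho(H3K9me3, TE frequency)    = {a['rho_frequency']:+.3f}  (p {a['p_frequency']:.2g})")
print(f"rho(H3K9me3, TE piRNA)        = {a['rho_pirna']:+.3f}  (p {a['p_pirna']:.2g})")
print(
    "by distance tertile: short %+.3f  intermediate %+.3f  long %+.3f"
    % (a["rho_pirna_short"], a["rho_pirna_intermediate"], a["rho_pirna_long"])
)

pairs = records[~records["nearest_te_tie"] & records["nearest_te_id"].notna()].copy()
pairs["h3k9_density"] = pairs[f"h3k9_{stage}"]
model = ts.logistic_frequency_model(
    pairs.rename(columns={"nearest_te_observed": "observed"}).dropna(
        subset=["observed", "h3k9_density", "recomb_rate"]
    ).assign(observed=lambda d: d["observed"].astype(bool))
)
print("\nlogistic model of TE presence in the population (backward AIC):")
print("retained terms:", model.terms or "none (AIC removed all predictors)")
print("coefficients:", {k: round(v, 3) for k, v in model.coefficients.items()})
print(
    "\nNegative H3K9me3-frequency and H3K9me3-distance correlations, with a\n"
    "positive piRNA correlation strongest for the closest pairs: the\n"
    "signature of selection against TEs that spread heterochromatin into\n"
    "genes.  The rank correlations detect this signal at sample sizes where\n"
    "the quadratic logistic model may still drop its predictors by AIC."
)
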