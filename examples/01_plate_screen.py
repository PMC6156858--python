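"""Normalize a single-dose plate screen, QC it, and call hits.

Simulates a 300-compound screen (96-well plates, quadruplicate vehicle and
cytotoxic-QC control wells per plate, 5% multiplicative well noise), converts
raw signals to percent inhibition anchored on each plate's own controls,
computes per-plate Z' factors, and calls hits above 70% inhibition.
"""

from acidscreen import screen, synthdata

plates, truth = synthdata.gen_screen_plates(n_compounds=300, noise_cv=0.05, seed=7)
results = screen.normalize_screen(plates)
hits = screen.call_hits(results, threshold=70.0)

print(f"screened {len(results)} compounds on {results['plate_id'].nunique()} plates")
zf = results.groupby("plate_id")["zfactor"].first()
print(f"plate Z' range {zf.min():.2f}-{zf.max():.2f} (>= 0.5 means a robust assay window)")
print(f"{len(hits)} hits above 70% inhibition; strongest:")
print(hits.head(5)[["compound_id", "pct_inhibition"]].to_string(index=False))

true_hits = set(truth.loc[truth["is_true_hit"], "compound_id"])
print(f"planted hits recovered: {len(set(hits['compound_id']) & true_hits)}/{len(true_hits)}")
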