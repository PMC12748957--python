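"""The preprocessing chain: analysis window, windowing, robust-arctan
scaling, [0, pi] remap and Pearson channel pruning.

Each 30 s trial is truncated to the 3-15 s post-stimulus segment (where
the hemodynamic response is expected) and cut into 12 non-overlapping
10-sample windows. Scaling is arctan((x - Q2)/(Q3 - Q1)) per channel —
median-centred, IQR-normalized, outlier-bounded — then shifted into
[0, pi] for angle embedding. For the amplitude-embedding classifier the
two channels least correlated with the label are dropped (27 -> 25
channels, 250 features).
"""

import numpy as np

from qfnirs import (
    SynthConfig,
    apply_robust_arctan,
    extract_analysis_window,
    fit_robust_scaler,
    make_windows,
    rescale_to_embedding_range,
    select_channels_pearson,
    simulate_dataset,
)

# channels 22 and 24 carry no class effect in the default stated world
trials = simulate_dataset(SynthConfig(seed=0))
windows = make_windows(extract_analysis_window(trials))
X, y, _, _ = windows.flat()
print(f"windows: {X.shape[0]} of shape {X.shape[1:]} "
      f"({windows.windows_per_trial} per trial)")

scaler = fit_robust_scaler(X)
scaled = apply_robust_arctan(X, scaler)
print(f"scaled range: ({scaled.min():.3f}, {scaled.max():.3f})  "
      f"— strictly inside (-pi/2, pi/2) despite raw range "
      f"({X.min():.0f}, {X.max():.0f})")

embedded = rescale_to_embedding_range(scaled)
print(f"embedding range: [{embedded.min():.3f}, {embedded.max():.3f}] in [0, pi]")

kept, dropped, scores = select_channels_pearson(scaled, y)
print(f"dropped channels (lowest |Pearson r| with the label): {dropped}")
print(f"kept {len(kept)} channels -> {len(kept) * 10} features "
      f"for amplitude embedding on 8 qubits (6 padding values)")
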