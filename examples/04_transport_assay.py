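"""Quantifying a FRET-based lipid transport assay.

A donor liposome population carries the fluorescent lipid sensor quenched by
an acceptor dye; as the transfer protein moves ligand to acceptor liposomes,
the signal dequenches exponentially.  The analysis normalizes the trace with
the F0/Fmax anchors, converts it to µM ligand delivered, fits the initial
rate over the first eight points (4 s) after protein injection, and recovers
the underlying rate constant.
"""

import numpy as np

import lipswitch as lw

# 200 uM total lipids with 5% ligand in the outer leaflet -> 5 uM accessible;
# 0.2 uM transfer protein
config = lw.AssayConfig(
    total_lipid=200.0, ligand_mole_fraction=0.05,
    accessible_fraction=0.5, protein_conc=0.2,
)
print(f"accessible ligand: {lw.accessible_concentration(config):.1f} uM")

trace, truth = lw.simulate_transport_trace(
    k=0.05, F0=100.0, Fmax=600.0, t_inject=10.0,
    noise_sd=5.0, dt=0.5, duration=120.0, seed=4, config=config,
)
print(f"simulated trace: {len(trace)} samples, true k = {truth.k} /s")

import warnings

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # noise can push F_Norm slightly past 1
    result = lw.initial_rate(trace, config)
print(
    f"initial rate: {result.initial_rate:.3f} uM/s over the first 8 points "
    f"after injection (R^2 = {result.r_squared:.3f})"
)
print(
    f"per-protein rate: {result.per_protein_rate:.1f} lipids/min per protein "
    f"(slope x 60 / [protein])"
)

k_hat, diag = lw.fit_transfer_k(trace)
print(f"fitted rate constant: k = {k_hat:.4f} /s (se {diag['stderr']:.1e})")
print(f"true initial rate (accessible x k): {truth.true_initial_rate:.2f} uM/s")
# The OLS rate sits below accessible x k because the exponential already
# bends over the finite 4 s window; the k fit recovers the constant itself.
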