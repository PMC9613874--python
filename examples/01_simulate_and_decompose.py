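"""Simulate a small complex-valued multi-subject fMRI tensor and decompose it.

Builds a noiseless 500-voxel, 80-timepoint, 8-subject dataset with 3
spatial sources and planted integer hemodynamic delays, runs the
constrained decomposition (phase sparsity + orthonormality + shift
invariance), and prints the matched-component recovery metrics.
"""

import numpy as np

from shiftcpd import SolverConfig, match_components, run_sarrr1lspo
from shiftcpd.simulate import SimConfig, generate_dataset

cfg = SimConfig(
    n_subjects=8, n_components=3, grid=(26, 26), n_voxels=500,
    n_timepoints=80, snr_db=np.inf, translation=0.0, rotation=0.0,
    spread=0.0, max_delay=5, seed=7,
)
X, truth = generate_dataset(cfg)
print(f"tensor: {X.shape[0]} voxels x {X.shape[1]} time points x {X.shape[2]} subjects")

factors, report = run_sarrr1lspo(X, SolverConfig(R=3, seed=3, n_runs=3, iter_max=200))
print(f"converged after {report.n_iter} iterations, final cost {report.final_fit:.4g}")

res = match_components(factors, truth)
for r in range(3):
    print(
        f"component {r}: |rho| SM={res.sm_magnitude[r]:.4f} "
        f"TC={res.tc_magnitude[r]:.4f} intensity={res.intensity[r]:.4f} "
        f"delays correct {res.n_correct_delays[r]}/{X.shape[2]}"
    )
# each |rho| compares an estimated factor with its matched ground-truth
# reference (1.0 = perfect); delay counts are exact integer matches after
# removing the per-component circular lag indeterminacy
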