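"""Simulate adoptive T-cell transfer across a TCR-pMHC affinity gradient.

Donor T cells (no intrinsic tumor wiring) are appended to a synthetic tumor
microenvironment and coupled to malignant cells through a pseudo
ligand-receptor pair: pMHC at TPM 5000 on tumor cells, TCR at a sweep of
levels on the transferred cells.  Each level re-runs the whole pipeline.
"""

import pseudospace as ps

host, lr, _ = ps.generate(ps.tumor_benchmark_spec(seed=0))
donor = ps.donor_t_cells(60, seed=100)

sweep = ps.transfer_sweep(
    host, lr, donor, [0.0, 500.0, 5000.0, 50000.0], target_cluster="malignant", seed=0
)
print(sweep.round(2).to_string(index=False))
r2 = sweep.attrs["r2"]
print(f"linear fit R^2, tumor-T connections:  {r2['pct_connections']['linear']:.2f}")
print(f"log fit R^2, infiltrating T cells:    {r2['pct_infiltrating_T']['log']:.2f}")

# Infiltration switches on once the pseudo TCR-pMHC affinity competes with
# the host's own ligand-receptor wiring and saturates at 100% of donors.
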