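"""Reference X-H bond-length tables for the comparison-statistics demo.

Published bond-length comparison tables for 1-methyluracil serve as worked
input for the ME/RMSD machinery: each column lists the five X-H distances
(A) from a refinement with a given scattering model, against neutron
reference values.  The kinematical table is referenced to 15 K neutron
geometry, the dynamical one to 60 K.
"""

from __future__ import annotations

from .refine import mean_error, rmsd

XH_BOND_LABELS = ["N3-H3", "C5-H5", "C6-H6", "C7-H7a", "C7-H7b"]

#: kinematical refinements against simulated data; reference: neutron, 15 K
KINEMATICAL_XH = {
    "reference": [1.0425, 1.0812, 1.0877, 1.0826, 1.0878],
    "IAM": [1.045, 1.101, 1.111, 1.102, 1.113],
    "TAAM": [1.043, 1.076, 1.080, 1.078, 1.0915],
    "molecule-TAAM": [1.030, 1.084, 1.098, 1.092, 1.087],
    "crystal-TAAM": [1.0467, 1.0727, 1.0790, 1.074, 1.0989],
}

#: dynamical refinements against experimental data; reference: neutron, 60 K
DYNAMICAL_XH = {
    "reference": [1.0408, 1.0794, 1.0884, 1.0817, 1.0858],
    "IAM": [1.065, 1.086, 1.122, 1.120, 1.220],
    "TAAM": [1.074, 1.053, 1.054, 1.078, 1.091],
    "crystal-TAAM": [1.084, 1.067, 1.127, 1.070, 1.100],
}


def xh_statistics(table: dict) -> dict:
    """ME and RMSD of every model column against the reference column."""
    reference = table["reference"]
    out = {}
    for model, lengths in table.items():
        if model == "reference":
            continue
        out[model] = {"me": mean_error(lengths, reference),
                      "rmsd": rmsd(lengths, reference)}
    return out
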