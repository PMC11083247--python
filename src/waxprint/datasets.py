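"""Bundled example data.

``load_headspace_bbd`` returns the published three-factor Box-Behnken
headspace-optimization study for paraffin-wax odor grading: incubation
temperature (100/120/140 degC), agitation (250/500/750 rpm) and sample
quantity (0.2/0.4/0.6 g), with the Euclidean distance between the
normalized total ion spectra of a Slight-odor and a Very-Strong-odor wax
as the response. 12 edge runs plus 6 center replicates.
"""

from __future__ import annotations

import numpy as np

from .doe import BbdStudy, FactorDef, bbd_design

__all__ = ["HEADSPACE_FACTORS", "load_headspace_bbd", "HEADSPACE_BBD_PREDICTED"]

HEADSPACE_FACTORS = (
    FactorDef("temperature", 100.0, 120.0, 140.0, "degC"),
    FactorDef("agitation", 250.0, 500.0, 750.0, "rpm"),
    FactorDef("sample_quantity", 0.2, 0.4, 0.6, "g"),
)

# run: (X1, X2, X3, measured distance)
_RUNS = (
    (-1, 0, 1, 0.056794),
    (1, -1, 0, 0.111667),
    (-1, -1, 0, 0.0546288),
    (1, 0, -1, 0.0695383),
    (1, 1, 0, 0.105074),
    (1, 0, 1, 0.1244),
    (0, -1, -1, 0.0580481),
    (-1, 1, 0, 0.0492514),
    (0, -1, 1, 0.0918902),
    (0, 1, 1, 0.0831786),
    (-1, 0, -1, 0.0539537),
    (0, 1, -1, 0.0876625),
    (0, 0, 0, 0.0808236),
    (0, 0, 0, 0.0825085),
    (0, 0, 0, 0.0898495),
    (0, 0, 0, 0.0641407),
    (0, 0, 0, 0.0892545),
    (0, 0, 0, 0.0922287),
)

#: Model-predicted responses as printed in the study report (for cross-checks).
HEADSPACE_BBD_PREDICTED = np.array(
    [0.0495423, 0.103849, 0.0542285, 0.07679, 0.105474, 0.124565,
     0.0586143, 0.0570693, 0.0995423, 0.0826123, 0.0537878, 0.0800104,
     0.0831342, 0.0831342, 0.0831342, 0.0831342, 0.0831342, 0.0831342]
)


def load_headspace_bbd() -> BbdStudy:
    """The bundled headspace Box-Behnken study, responses included.

    Run ordering matches the published table, which differs from the
    constructor's canonical edge ordering, so the design rows are set
    explicitly here.
    """
    skeleton = bbd_design(HEADSPACE_FACTORS, n_center=6)
    design = skeleton.design.copy()
    coded = np.array([r[:3] for r in _RUNS], dtype=float)
    design.loc[:, ["X1", "X2", "X3"]] = coded
    responses = np.array([r[3] for r in _RUNS])
    return BbdStudy(HEADSPACE_FACTORS, design, responses, skeleton.run_order)
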