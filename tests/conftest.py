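"""Shared fixtures: phantom geometry, a seeded cohort and its boundary maps."""

from __future__ import annotations

import numpy as np
import pytest

import gwboundary as gwb
from gwboundary import boundary as bnd
from gwboundary import normative as nrm

COHORT_SEED = 1


@pytest.fixture(scope="session")
def spec() -> gwb.PhantomSpec:
    return gwb.PhantomSpec()


@pytest.fixture(scope="session")
def atlas(spec):
    return gwb.make_toy_atlas(spec)


@pytest.fixture(scope="session")
def cohort10(spec):
    """10 CN / 10 MCI / 10 AD phantom cohort under the default study conditions."""
    return gwb.make_cohort(gwb.default_cohort_spec(10, 10, 10, seed=COHORT_SEED), spec)


@pytest.fixture(scope="session")
def densities10(cohort10):
    """Convolved (5x5x5 box) boundary maps for every cohort subject."""
    out = {}
    for sid in cohort10.table["subject_id"]:
        t1 = cohort10.volumes[sid]
        frac = cohort10.fractions[sid]
        thr = bnd.compute_thresholds(t1, frac)
        gwbb = bnd.compute_gwbb(t1, frac, thr)
        out[sid] = bnd.box_convolve(gwbb, kernel_size=5)
    return out


@pytest.fixture(scope="session")
def cn_model(cohort10, densities10):
    cn_ids = cohort10.table.loc[cohort10.table["group"] == "CN", "subject_id"]
    return nrm.build_normative([densities10[s] for s in cn_ids])


@pytest.fixture(scope="session")
def shell_zscores(cohort10, densities10, cn_model, atlas):
    """Boundary-shell-ROI mean gwBZ per subject, aligned with the cohort table."""
    shell = atlas.labels.data == 1
    vals = []
    for sid in cohort10.table["subject_id"]:
        z = nrm.zscore(densities10[sid], cn_model)
        vals.append(float(z.data.data[shell].mean()))
    return np.asarray(vals)
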