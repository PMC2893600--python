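import numpy as np
import pandas as pd
import pytest

from xmask.io import ProbeIntensityMatrix, ProbeSetMap, SampleSheet
from xmask.simulate import SimConfig, generate

#: octave-spaced threshold grid used by recovery experiments; one step
#: matches the resolution of the maximin threshold picker
OCTAVE_GRID = [5.0, 10.0, 20.0, 40.0, 80.0, 160.0, 320.0, 640.0]


def make_sheet(n_genotypes=2, replicates=3, species="target"):
    rows = []
    genotypes = ["A", "B"][:n_genotypes]
    for geno in genotypes:
        for tissue in ("ES", "PES"):
            for rep in range(1, replicates + 1):
                rows.append((f"{species[0]}_{geno}_{tissue}_{rep}", species, geno,
                             tissue, rep))
    return SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "species", "genotype", "tissue", "replicate"]))


def make_matrix(values, sheet=None, scale="linear"):
    """Probe matrix from a 2D array; probe ids p000, p001, ..."""
    values = np.asarray(values, dtype=float)
    if sheet is None:
        sheet = make_sheet(replicates=max(1, values.shape[1] // 4))
    df = pd.DataFrame(values, columns=sheet.sample_ids,
                      index=pd.Index([f"p{i:03d}" for i in range(len(values))],
                                     name="probe_id"))
    return ProbeIntensityMatrix(df, sheet, scale)


def make_map(n_sets, probes_per_set):
    rows = []
    for g in range(n_sets):
        for j in range(probes_per_set):
            rows.append((f"p{g * probes_per_set + j:03d}", f"ps{g:03d}", j + 1))
    return ProbeSetMap(pd.DataFrame(rows, columns=["probe_id", "probeset_id",
                                                   "probe_index"]))


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic dataset shared by IO/pipeline tests."""
    return generate(SimConfig(n_probesets=60, seed=11, sfp_probe_count=45,
                              sfp_probes_per_set=9))
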