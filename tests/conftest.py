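import numpy as np
import pytest

from soasr.kinetics import IncubationSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240620)


def make_series(times, values, analyte="As(III)", site="FK", treatment="As+S",
                replicate="r1", basis="volume", **extra):
    conc = {analyte: np.asarray(values, dtype=float)}
    for name, vec in extra.items():
        conc[name] = np.asarray(vec, dtype=float)
    return IncubationSeries(
        site=site, treatment=treatment, replicate=replicate,
        timepoints=np.asarray(times, dtype=float), concentrations=conc, basis=basis,
    )
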