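import warnings

import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from photoscreen import SimConfig, SensitizerSpec, blank_correct, simulate_dma_plate

LAYOUT_CSV = """well,sample_id,arm,concentration_ug_per_ml,replicate
A1,ext1,dma_probe,,1
A2,ext1,extract_alone,,1
A3,ext1,dma_plus_quencher,,1
A4,ext1,extract_plus_quencher,,1
B1,solvent,solvent_control,,1
B2,berberine,reference_ps,,1
"""

# four 377 nm readings per well at doses 0/6.2/12.4/24.7 (24 records)
READINGS_CSV = "well,wavelength_nm,cumulative_dose_J_cm2,od\n" + "".join(
    f"{well},377,{dose},{od}\n"
    for well, start, step in [
        ("A1", 0.40, -0.05),
        ("A2", 0.10, 0.0),
        ("A3", 0.40, -0.01),
        ("A4", 0.10, 0.0),
        ("B1", 0.40, -0.002),
        ("B2", 0.40, -0.03),
    ]
    for i, dose in enumerate([0.0, 6.2, 12.4, 24.7])
    for od in [round(start + i * step, 4)]
)


@pytest.fixture
def plate_files(tmp_path):
    layout = tmp_path / "layout.csv"
    readings = tmp_path / "readings.csv"
    layout.write_text(LAYOUT_CSV)
    readings.write_text(READINGS_CSV)
    return layout, readings


@pytest.fixture
def seeded_plate():
    """Simulated plate with one strong, one null and one unquenchable extract."""
    specs = [
        SensitizerSpec("strong", a_irr=0.5, effective_phi=2.05),
        SensitizerSpec("null", a_irr=0.3, effective_phi=0.0),
        SensitizerSpec("type1", a_irr=0.4, effective_phi=1.0, quenchable=0.0),
    ]
    ds = simulate_dma_plate(specs, SimConfig(seed=11))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return blank_correct(ds)
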