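import hypothesis
import pandas as pd
import pytest

from siscreen import ScreenSimConfig, generate_screen, write_plate_table

hypothesis.settings.register_profile(
    "siscreen", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("siscreen")


PLATE_HEADER = "plate,batch,row,col,perturbation,co_treatment,viability,count"


def make_plate_csv(path, rows):
    path.write_text(PLATE_HEADER + "\n" + "\n".join(rows) + "\n")
    return path


@pytest.fixture
def tiny_plate_csv(tmp_path):
    """A single valid plate with 3 siNC, 3 siPLK1 and 2 gene wells."""
    rows = [
        "P1,1,A,1,GENEA,VEHICLE,800,400",
        "P1,1,B,1,GENEB,VEHICLE,3000,1500",
        "P1,1,A,23,NC,VEHICLE,3200,1600",
        "P1,1,B,23,NC,VEHICLE,3100,1550",
        "P1,1,C,23,NC,VEHICLE,3300,1650",
        "P1,1,A,24,PLK1,VEHICLE,420,210",
        "P1,1,B,24,PLK1,VEHICLE,380,190",
        "P1,1,C,24,PLK1,VEHICLE,400,200",
    ]
    return make_plate_csv(tmp_path / "plate.csv", rows)


@pytest.fixture(scope="session")
def noiseless_screen():
    """12-gene screen with a -2 log2 planted effect and zero noise."""
    cfg = ScreenSimConfig(
        n_genes=12,
        planted_effects={"G001": (-2.0, -2.0)},
        count_noise_cv=0.0,
        viability_noise_cv=0.0,
        batch_shift_sd=0.0,
        seed=7,
    )
    return generate_screen(cfg)


@pytest.fixture(scope="session")
def default_screen():
    """12-gene screen at the generator's default noise settings."""
    return generate_screen(ScreenSimConfig(n_genes=12, seed=11))


@pytest.fixture
def cohort_csvs(tmp_path):
    """Hand-written 5-sample cohort; sample S5 lacks expression."""
    clinical = tmp_path / "clinical.csv"
    clinical.write_text(
        "sample_id,vital_status,days_to_death,days_to_last_follow_up,"
        "days_to_new_tumor_event,gender,stage\n"
        "S1,DEAD,300,,250,FEMALE,I\n"
        "S2,ALIVE,,900,,MALE,II\n"
        "S3,DEAD,120,,,FEMALE,III\n"
        "S4,ALIVE,,640,400,MALE,I\n"
        "S5,ALIVE,,720,,FEMALE,IV\n"
    )
    expression = tmp_path / "expression.csv"
    expression.write_text(
        "gene,S1,S2,S3,S4\n"
        "TACR3,5.1,1.2,4.8,0.9\n"
        "NPY,2.0,2.2,1.8,2.1\n"
    )
    mutations = tmp_path / "mutations.csv"
    mutations.write_text(
        "sample_id,gene\nS1,KRAS\nS1,TP53\nS3,KRAS\nS4,EGFR\n"
    )
    return clinical, expression, mutations
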