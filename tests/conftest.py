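"""Shared fixtures: a tiny hand-built two-study dataset (one 2-arm trial, one
3-arm trial -> 3 comparisons) written as the three-CSV schema."""

from pathlib import Path

import pytest

from ppcmeta import read_dataset

STUDIES_CSV = """\
study_id,age_mean,total_hours,training_weeks,mbi_name,rob_random_sequencing,rob_allocation,rob_blinding,rob_incomplete,rob_selective
s1,12.5,8,8,MBSR,low,low,unclear,low,high
s2,15.7,16,8,MBCT,low,low,low,low,high
"""

ARMS_CSV = """\
study_id,arm_id,role,control_subtype,n
s1,mbi,mbi,none,20
s1,ctl,control,wait_list,20
s2,mbi,mbi,none,30
s2,ctl1,control,no_contact,25
s2,ctl2,control,active_intervention,28
"""

# s1/c1 mindfulness FFMQ: S_pre = 2, d = (4 - 1)/2 = 1.5 (hand computed)
# s1/c1 depression CDI (lower better): raw d = -1.0, oriented +1.0
MEASURES_CSV = """\
study_id,comparison_id,mbi_arm_id,control_arm_id,measure_name,category,direction,mbi_pre_mean,mbi_pre_sd,mbi_post_mean,mbi_post_sd,mbi_n,ctl_pre_mean,ctl_pre_sd,ctl_post_mean,ctl_post_sd,ctl_n
s1,c1,mbi,ctl,FFMQ,mindfulness,higher_better,10,2,14,2.2,20,10,2,11,2.1,20
s1,c1,mbi,ctl,CAMM,mindfulness,higher_better,30,5,33,5.5,20,30,5,31,5.2,20
s1,c1,mbi,ctl,CDI,depression,lower_better,20,4,15,4,20,20,4,19,4,20
s2,c1,mbi,ctl1,STAI,anxiety_stress,lower_better,40,8,35,8,30,40,8,39,8,25
s2,c2,mbi,ctl2,STAI,anxiety_stress,lower_better,40,8,35,8,30,41,8,40,8,28
"""


def write_fixture_csvs(directory: Path) -> tuple[Path, Path, Path]:
    studies = directory / "studies.csv"
    arms = directory / "arms.csv"
    measures = directory / "measures.csv"
    studies.write_text(STUDIES_CSV)
    arms.write_text(ARMS_CSV)
    measures.write_text(MEASURES_CSV)
    return studies, arms, measures


@pytest.fixture
def csv_paths(tmp_path):
    return write_fixture_csvs(tmp_path)


@pytest.fixture
def dataset(csv_paths):
    return read_dataset(*csv_paths)
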