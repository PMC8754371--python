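"""Clinical characteristics of the 11-patient iEEG cohort.

Eleven drug-refractory epilepsy patients implanted with depth electrodes for
presurgical evaluation contributed the recordings this pipeline is designed
for.  State anxiety was assessed post-task with the State-Trait Anxiety
Inventory (STAI Form Y); one patient (10) has no STAI entry.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

_COHORT_TSV = """\
patient	sex	age	handedness	seizure_onset_age	n_aed	epileptogenic_zone	stai
1	M	25	L	10	3	R posttemporal	36
2	F	24	R	5	2	R temporooccipital	32
3	F	22	R	8	3	R basal temporal	29
8	F	28	R	24	2	R temporopolar and amygdalohippocampal	40
10	M	25	R	15	4	R temporooccipital
12	M	20	R	16	2	L basal temporal	21
14	M	48	R	22	2	R temporolateral and multifocal (R orbital, opercular)	38
15	M	37	L	1	3	R post- and lateral occipital	26
16	F	44	R	19	2	R basal temporal	35
17	M	31	R	12	3	R postsuperior temporal	26
18	F	31	R	26	2	L temporal periventricular	28
"""


def cohort_table() -> pd.DataFrame:
    """Per-patient demographics and clinical characteristics."""
    return pd.read_csv(io.StringIO(_COHORT_TSV), sep="\t")


def stai_summary() -> dict:
    """Mean and SEM of the available STAI state-anxiety scores.

    SEM uses the sample standard deviation (ddof=1) over the n patients with
    a reported score.
    """
    scores = cohort_table()["stai"].dropna().to_numpy(dtype=float)
    n = scores.size
    mean = float(scores.mean())
    sem = float(scores.std(ddof=1) / np.sqrt(n))
    return {"n": n, "mean": mean, "sem": sem}
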