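import numpy as np
import pytest

from th2score import Cohort, Participant

# Marker values chosen so the composite score is exactly k: markers are
# "elevated" in the fixed order feno, ige, bec, prick.
_ELEVATED = {"feno": 30.0, "ige": 150.0, "bec": 200.0}
_NORMAL = {"feno": 10.0, "ige": 50.0, "bec": 100.0}


def participant_with_score(pid: str, asthma: bool, k: int) -> Participant:
    """Participant whose composite score under default cutoffs equals k."""
    assert 0 <= k <= 4
    return Participant(
        id=pid,
        asthma=asthma,
        feno=_ELEVATED["feno"] if k >= 1 else _NORMAL["feno"],
        ige=_ELEVATED["ige"] if k >= 2 else _NORMAL["ige"],
        bec=_ELEVATED["bec"] if k >= 3 else _NORMAL["bec"],
        prick_positive=k >= 4,
    )


def build_crosstab_cohort(
    neg_low: int, pos_low: int, neg_high: int, pos_high: int
) -> Cohort:
    """Cohort whose score/diagnosis cross-tab at the score>2 rule is the
    given counts (rows: score<=2, score>2; columns: no-asthma, asthma)."""
    participants = []
    i = 0
    for _ in range(neg_low):
        participants.append(participant_with_score(f"p{i:03d}", False, 1)); i += 1
    for _ in range(pos_low):
        participants.append(participant_with_score(f"p{i:03d}", True, 2)); i += 1
    for _ in range(neg_high):
        participants.append(participant_with_score(f"p{i:03d}", False, 3)); i += 1
    for _ in range(pos_high):
        participants.append(participant_with_score(f"p{i:03d}", True, 3)); i += 1
    return Cohort(participants, provenance="crosstab-fixture")


@pytest.fixture
def crosstab_cohort() -> Cohort:
    """48-row cohort reproducing the published cross-tabulation 25,14 / 1,8."""
    return build_crosstab_cohort(25, 14, 1, 8)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
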