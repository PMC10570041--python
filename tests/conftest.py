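"""Shared fixtures: synthetic studies reused across test modules.

Heavy simulations are session-scoped so each is generated once per run.
"""

import numpy as np
import pytest

from guidevar import dualtarget as dt
from guidevar import synthdata as sd
from guidevar.offtarget import LookupGMT
from guidevar.ontarget import pretrain_encoder
from guidevar.seqfeat import MONO_ORDER, Spacer


def random_spacer(rng, length=20, id=""):
    return Spacer("".join(rng.choice(list("ACGT"), size=length)), id)


@pytest.fixture(scope="session")
def dual_study():
    """A dual-target study deep enough for parameter-recovery checks.

    1500 guides x 7 targets gives ~4500 single-mismatch pairs (~19 per IME
    cell) and ~4500 double-mismatch pairs (~24 per position-pair bin).
    """
    lib = sd.gen_library(1500, seed=31)
    truth = sd.make_truth(lib, seed=32)
    counts, pairs, dt_truth = sd.gen_dualtarget(lib, truth, depth=5000, seed=33)
    ratios = dt.counts_table_to_records(counts)
    one_ids = [p for p in ratios.index if pairs[p].n_mismatches == 1]
    two_ids = [p for p in ratios.index if pairs[p].n_mismatches == 2]
    return {
        "library": lib,
        "truth": truth,
        "counts": counts,
        "pairs": pairs,
        "ratios": ratios,
        "dt_truth": dt_truth,
        "one_ids": one_ids,
        "two_ids": two_ids,
        "gmt": LookupGMT(truth.gmt, default=1.0),
    }


@pytest.fixture(scope="session")
def screen_study():
    """Deep-coverage triple screen (WT/HiFi/LZ3) for one seeded library."""
    lib = sd.gen_library(1200, seed=11)
    truth = sd.make_truth(lib, seed=12)
    screens = {
        enz: sd.gen_screen(lib, truth, enz, depth=2000, nb_size=300, seed=13 + k)
        for k, enz in enumerate(dt.ENZYMES)
    }
    return {"library": lib, "truth": truth, "screens": screens}


@pytest.fixture(scope="session")
def pretrain_task():
    """A planted sequence-to-efficiency task the encoders can learn.

    The target depends on the nucleotide content of PAM-proximal positions
    1-5 through fixed random weights.
    """
    rng = np.random.default_rng(7)
    w = rng.normal(0.0, 1.0, size=(4, 5))
    spacers = [random_spacer(rng, id=f"pt{i}") for i in range(800)]

    def f(s: Spacer) -> float:
        return sum(w[MONO_ORDER.index(s.base_at(p)), p - 1] for p in range(1, 6))

    y = np.array([f(s) for s in spacers])
    return {"spacers": spacers, "y": y, "f": f, "weights": w}


@pytest.fixture(scope="session")
def trained_encoders(pretrain_task):
    """Two pretrained, frozen BiLSTM encoders sharing the planted task."""
    sp, y = pretrain_task["spacers"][:600], pretrain_task["y"][:600]
    enc1 = pretrain_encoder(sp, y, hidden=24, epochs=200, seed=3, task_tag="WT-task")
    enc2 = pretrain_encoder(sp, y, hidden=24, epochs=200, seed=4, task_tag="HF1-task")
    return enc1, enc2
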