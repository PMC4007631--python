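import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import medipdiff as md
from medipdiff import probestats, promoters

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> md.SimulationConfig:
    return md.SimulationConfig(n_promoters=600, n_mirnas=30, seed=101)


@pytest.fixture(scope="session")
def small_data(small_cfg):
    """One desk-scale synthetic cohort shared by read-only tests."""
    layout = md.generate_genome_layout(small_cfg)
    truth = md.simulate_truth(layout, small_cfg)
    bound, input_, sheet = md.simulate_arrays(layout, truth, small_cfg)
    mm = md.quantile_normalize(md.compute_log_ratios(bound, input_))
    avg = md.average_replicates(mm, sheet)
    stats, eb = probestats.probe_statistics(avg.values, sheet)
    stats["promoter_id"] = (
        layout.probes.set_index("probe_id")["promoter_id"].reindex(stats.index)
    )
    calls = promoters.call_promoters(stats)
    return dict(
        cfg=small_cfg, layout=layout, truth=truth, bound=bound, input=input_,
        sheet=sheet, mm=mm, avg=avg, stats=stats, eb=eb, calls=calls,
    )


def run_two_tier(cfg: md.SimulationConfig):
    """Simulate one cohort and run it through probe stats + promoter calls."""
    layout = md.generate_genome_layout(cfg)
    truth = md.simulate_truth(layout, cfg)
    bound, input_, sheet = md.simulate_arrays(layout, truth, cfg)
    avg = md.average_replicates(
        md.quantile_normalize(md.compute_log_ratios(bound, input_)), sheet
    )
    stats, _ = probestats.probe_statistics(avg.values, sheet)
    stats["promoter_id"] = (
        layout.probes.set_index("probe_id")["promoter_id"].reindex(stats.index)
    )
    calls = promoters.call_promoters(stats)
    avg.values.attrs["promoter_ids"] = stats["promoter_id"].to_numpy()
    return layout, truth, sheet, avg, stats, calls
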