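import warnings

import numpy as np
import pytest

from ionexome import core, line_filter, simdata


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """An 8-line simulated cohort with a 300-variant shared background.

    Returns (cfg, genome, models, targets, truth, paths).
    """
    cfg = simdata.SimConfig(rng_seed=7, n_lines=8, n_shared_background=300)
    rng = np.random.default_rng(7)
    genome, models, targets = simdata.make_genome_and_targets(cfg, rng)
    out = tmp_path_factory.mktemp("cohort")
    truth, paths = simdata.inject_variants(cfg, genome, targets, out, models=models, rng=rng)
    return cfg, genome, models, targets, truth, paths


@pytest.fixture(scope="session")
def small_cohort_callsets(small_cohort):
    """Ingested call sets (both callers) for the small cohort."""
    _, _, _, _, _, paths = small_cohort
    cohort = []
    for line_id, p in paths.items():
        cohort.append(core.read_vcf(p["vcf"], line_id))
        cohort.append(core.read_pindel(p["pindel"], line_id))
    return cohort


@pytest.fixture(scope="session")
def small_cohort_filtered(small_cohort, small_cohort_callsets):
    """Pipeline output on the small cohort: (per_line, report)."""
    _, genome, _, targets, _, _ = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return line_filter.extract_line_specific(
            small_cohort_callsets, reference=genome, targets=targets
        )
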