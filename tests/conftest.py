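import numpy as np
import pytest

from twindiff.types import ExpressionStudy, TwinPair


def study_from_diffs(diffs, study_id="S1", genes=None, sex=None, base=None):
    """Build a study whose within-pair differences are exactly ``diffs``.

    ``diffs`` is probe × pair; the unaffected twin gets ``base`` (default 0)
    and the affected twin ``base + diff``, so the paired statistics see the
    requested differences. ``genes`` maps probe index -> gene symbol(s).
    """
    diffs = np.asarray(diffs, dtype=float)
    n_probes, n_pairs = diffs.shape
    if base is None:
        base = np.zeros_like(diffs)
    probe_ids = [f"p{i}" for i in range(n_probes)]
    sample_ids, pairs = [], []
    values = np.empty((n_probes, 2 * n_pairs))
    for j in range(n_pairs):
        sample_ids += [f"t{j}a", f"t{j}u"]
        pairs.append(TwinPair(f"pair{j}", f"t{j}a", f"t{j}u"))
        values[:, 2 * j] = base[:, j] + diffs[:, j]
        values[:, 2 * j + 1] = base[:, j]
    if genes is None:
        genes = {i: f"g{i}" for i in range(n_probes)}
    annotation = {}
    for i, g in genes.items():
        annotation[probe_ids[i]] = frozenset([g] if isinstance(g, str) else g)
    return ExpressionStudy(study_id=study_id, phenotype=study_id,
                           probe_ids=probe_ids, sample_ids=sample_ids,
                           values=values, pairs=pairs, sex=sex,
                           annotation=annotation)


@pytest.fixture
def small_study():
    """4 probes x 3 pairs with simple known differences."""
    rng = np.random.default_rng(7)
    return study_from_diffs(rng.normal(0, 1, size=(4, 5)))


@pytest.fixture
def tiny_cohort():
    """A small simulated 3-study cohort with ground truth (seeded)."""
    from twindiff.simulate import SimulationConfig, simulate_cohort
    cfg = SimulationConfig(
        n_studies=3, pairs_per_study=(10, 12, 8), phenotypes=("A", "B", "C"),
        n_genes_universe=300, platform_coverage=0.8, probes_per_gene=(1, 3),
        frac_affected_genes=0.1, effect_mean_sd=40.0, tau=5.0, noise_sd=30.0,
        pair_effect_sd=30.0, probe_offset_sd=10.0,
        sex_labelled_studies=(0, 1, 2), seed=11)
    return simulate_cohort(cfg)
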