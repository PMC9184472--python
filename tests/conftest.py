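import pandas as pd
import pytest
from hypothesis import settings

from exonqpcr import synth
from exonqpcr.model import Config, Dataset, records_frame, CtRecord

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return Config()


@pytest.fixture(scope="session")
def scenario_dataset():
    """One draw of the study-emulating scenario (shared, read-only)."""
    dataset, truth = synth.generate(synth.study_scenario(seed=0))
    return dataset, truth


def make_tiny_dataset(rows, manifest_rows, config=None):
    """Build a dataset from (donor, dose, time, gene, assay, replicate, ct)
    tuples; ct=None means censored."""
    config = config or Config()
    records = records_frame(
        [
            CtRecord(
                sample_id=f"{d}_{x:g}Gy_{t:g}h",
                donor_id=d, dose_gy=x, time_h=t,
                gene=g, assay_id=a, replicate=r, ct=ct,
            )
            for (d, x, t, g, a, r, ct) in rows
        ]
    )
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["assay_id", "gene", "exon_region_index", "design_suffix",
                 "best_coverage"],
    )
    return Dataset(records=records, manifest=manifest, config=config)


def grid_rows(assay_fc, baselines, genes, hk_id="Hs03003631_g1",
              donors=("d1", "d2", "d3"), doses=(0.0, 0.5, 4.0),
              times=(24.0, 48.0), reps=(1, 2), hk_ct=10.0):
    """Noise-free full-factorial Ct rows implied by exact fold changes.

    ``assay_fc``: assay -> {(dose, time): fc} (reference dose is 1).
    """
    rows = []
    import math
    for d in donors:
        for x in doses:
            for t in times:
                for r in reps:
                    rows.append((d, x, t, "18S", hk_id, r, hk_ct))
                    for assay, profile in assay_fc.items():
                        fc = 1.0 if x == 0.0 else profile.get((x, t), 1.0)
                        ct = baselines[assay] - math.log2(fc)
                        rows.append((d, x, t, genes[assay], assay, r, ct))
    return rows
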