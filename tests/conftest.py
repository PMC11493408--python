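import numpy as np
import pandas as pd
import pytest

from dgrpkit.panel import (
    PhenotypeDescriptor,
    PhenotypeRegistry,
    PhenotypeTable,
    StudyMeta,
)


def make_registry(studies: dict, statuses: dict | None = None,
                  categories: dict | None = None,
                  units: dict | None = None,
                  dtypes: dict | None = None) -> PhenotypeRegistry:
    """Build a registry from {study_id: {sex: {pheno_id: {line: value}}}}.

    ``units``/``dtypes`` override per (study, pheno, sex) tuples.
    """
    statuses = statuses or {}
    categories = categories or {}
    units = units or {}
    dtypes = dtypes or {}
    reg = PhenotypeRegistry()
    for sid, by_sex in studies.items():
        pheno_ids = sorted({p for d in by_sex.values() for p in d})
        rows = []
        descriptors = []
        for sex in sorted(by_sex):
            lines = sorted({l for vals in by_sex[sex].values() for l in vals})
            block = {"line_id": lines, "sex": sex}
            for pid in pheno_ids:
                vals = by_sex[sex].get(pid, {})
                block[pid] = [vals.get(l, np.nan) for l in lines]
            rows.append(pd.DataFrame(block))
            for pid in pheno_ids:
                if pid in by_sex[sex]:
                    key = (sid, pid, sex)
                    descriptors.append(PhenotypeDescriptor(
                        study_id=sid, phenotype_id=pid, name=pid, sex=sex,
                        unit=units.get(key, "a.u."),
                        dtype=dtypes.get(key, "quantitative"),
                    ))
        table = PhenotypeTable(study_id=sid, data=pd.concat(rows, ignore_index=True))
        meta = StudyMeta(study_id=sid, title=sid,
                         categories=tuple(categories.get(sid, ())),
                         status=statuses.get(sid, "curated"))
        reg.add_study(meta, table, descriptors)
    return reg


@pytest.fixture
def tiny_registry():
    """Two curated studies, full line overlap, distinct value patterns."""
    lines = [f"DGRP_{i:03d}" for i in range(1, 9)]
    rng = np.random.default_rng(7)
    studies = {}
    for sid in ("S1", "S2"):
        by_sex = {}
        for sex in ("F", "M"):
            by_sex[sex] = {
                pid: {l: float(v) for l, v in zip(lines, rng.normal(size=len(lines)))}
                for pid in ("p1", "p2")
            }
        studies[sid] = by_sex
    return make_registry(studies)
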