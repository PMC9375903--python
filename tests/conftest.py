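import numpy as np
import pytest

from ddirel import synthetic_data as sd

TOY_XML = """<?xml version="1.0" encoding="UTF-8"?>
<corpus>
 <document id="d1">
  <sentence id="d1.s0" text="alosetron inhibits isoniazid and procainamide">
   <entity id="d1.s0.e0" charOffset="0-8" type="drug" text="alosetron"/>
   <entity id="d1.s0.e1" charOffset="19-27" type="drug" text="isoniazid"/>
   <entity id="d1.s0.e2" charOffset="33-44" type="drug" text="procainamide"/>
   <pair id="d1.s0.p0" e1="d1.s0.e0" e2="d1.s0.e2" ddi="true" type="effect"/>
   <pair id="d1.s0.p1" e1="d1.s0.e0" e2="d1.s0.e1" ddi="false"/>
   <pair id="d1.s0.p2" e1="d1.s0.e1" e2="d1.s0.e2" ddi="false"/>
  </sentence>
 </document>
</corpus>
"""


@pytest.fixture
def toy_xml(tmp_path):
    path = tmp_path / "toy.xml"
    path.write_text(TOY_XML)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus():
    """60 trigger-between sentences plus a matching drug table."""
    _, instances = sd.generate_corpus(sd.GeneratorSpec(n_sentences=60, seed=7))
    table = sd.generate_drug_table(12, seed=7)
    return instances, table
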