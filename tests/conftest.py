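import numpy as np
import pytest

from protmr.summary_io import HarmonizedInstrument, VariantAssociation, harmonize
from protmr.synthetic import SyntheticScenario, simulate_protein_scenario


def mk_inst(bx, sx, by, sy, vid="rs1", eaf=0.3, **kw):
    return HarmonizedInstrument(
        variant_id=vid,
        beta_exposure=bx,
        se_exposure=sx,
        beta_outcome=by,
        se_outcome=sy,
        eaf=eaf,
        **kw,
    )


def mk_insts(bx, sx, by, sy, eaf=None):
    """Vector arguments -> list of instruments."""
    bx, sx, by, sy = map(np.atleast_1d, (bx, sx, by, sy))
    eaf = np.full(len(bx), 0.3) if eaf is None else np.atleast_1d(eaf)
    return [
        mk_inst(float(bx[i]), float(sx[i]), float(by[i]), float(sy[i]),
                vid=f"rs{i}", eaf=float(eaf[i]))
        for i in range(len(bx))
    ]


def mk_variant(vid="rs1", chrom="1", pos=100, ea="A", oa="G", beta=0.1,
               se=0.01, pvalue=1e-10, n=10000.0, eaf=0.3, protein_id=None):
    return VariantAssociation(
        variant_id=vid, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        beta=beta, se=se, pvalue=pvalue, n=n, eaf=eaf, protein_id=protein_id,
    )


def scenario_instruments(**kwargs):
    """Simulate one cohort and return harmonized instruments."""
    scn = SyntheticScenario(**kwargs)
    sim = simulate_protein_scenario(scn)[0]
    return harmonize(sim.exposure, {r.variant_id: r for r in sim.outcome})


@pytest.fixture
def clean_instruments():
    """30 pleiotropy-free instruments with true causal effect 0.3."""
    return scenario_instruments(
        theta=0.3, J=30, n_exposure=30_000, n_outcome=30_000, seed=21
    )
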