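import numpy as np
import pytest

from twosample_mr.harmonize import HarmonizedSet, HarmonizedVariant
from twosample_mr.sumstats import SummaryStatsTable, VariantAssociation


def make_variant(rsid="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
                 beta=0.1, se=0.02, pvalue=None, n=10000.0):
    if pvalue is None:
        from scipy import stats
        pvalue = max(float(2 * stats.norm.sf(abs(beta) / se)), 5e-324)
    return VariantAssociation(rsid, chrom, pos, ea, oa, eaf, beta, se, pvalue, n)


def make_table(records, trait="trait", trait_type="continuous"):
    return SummaryStatsTable(trait_name=trait, trait_type=trait_type,
                             records=list(records))


def hset_from_arrays(bx, sx, by, sy, exposure_type="continuous"):
    """HarmonizedSet straight from effect arrays (exposure betas must be >= 0)."""
    variants = [
        HarmonizedVariant(
            rsid=f"rs{i}", effect_allele="A", other_allele="G",
            beta_exp=float(bx[i]), se_exp=float(sx[i]),
            beta_out=float(by[i]), se_out=float(sy[i]),
            eaf_exp=0.5, eaf_out=0.5,
        )
        for i in range(len(bx))
    ]
    return HarmonizedSet("exp", "out", variants, exposure_type=exposure_type)


@pytest.fixture
def random_hset():
    """Factory for random harmonized sets with a known causal slope."""

    def _make(n_snps=20, theta=0.2, seed=0, pleio_sd=0.0):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.05, 0.5, n_snps)
        sx = rng.uniform(0.005, 0.02, n_snps)
        sy = rng.uniform(0.01, 0.05, n_snps)
        by = theta * bx + rng.normal(0, pleio_sd, n_snps) + rng.normal(0, sy)
        return hset_from_arrays(bx, sx, by, sy)

    return _make
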