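"""Packaged example data.

The bundled moments describe a published cross-sectional sample of 141
infertile couples: marital satisfaction (sum-scored 10-item scale, range
10-50) and anxiety (7-item hospital anxiety subscale, range 0-21) measured
on both members of each couple.  Means, SDs and correlations are stored
exactly as printed (correlations to 3 decimals), which is the accepted
input precision for every analysis in this package.
"""

from importlib import resources

import json

from ..dyad_data import SummaryMoments

__all__ = ["load_couples_moments"]


def load_couples_moments() -> SummaryMoments:
    """Summary moments for the example sample of 141 couples.

    Variable order: man's marital satisfaction, man's anxiety, woman's
    marital satisfaction, woman's anxiety.
    """
    path = resources.files(__name__).joinpath("couples_moments.json")
    return SummaryMoments.from_dict(json.loads(path.read_text()))
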