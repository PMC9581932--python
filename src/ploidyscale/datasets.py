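"""Small packaged reference inputs."""

from importlib import resources

import pandas as pd

from .scaling import PloidyMedianSeries


def load_ploidy_medians() -> PloidyMedianSeries:
    """Reported haploid-anchored per-ploidy proteome medians (1N-4N).

    The published quantification of the isogenic budding-yeast ploidy
    series: median relative proteome amount of 1.00, 1.61, 2.31 and 2.95
    for 1N-4N after anchoring the haploid median at 1.  These four points
    are the canonical worked example for the power-law fit.
    """
    path = resources.files("ploidyscale").joinpath("data/ploidy_medians.tsv")
    with resources.as_file(path) as p:
        frame = pd.read_csv(p, sep="\t")
    return PloidyMedianSeries(
        tuple(int(x) for x in frame["ploidy"]),
        tuple(float(x) for x in frame["median_relative_amount"]),
    )
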