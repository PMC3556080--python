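"""Published reference inputs bundled with the package.

The consensus profile below is the reported eight-gene outcome of a GIST
imatinib-sensitization knockdown panel: genes found consistently regulated
across all 14 knockdown samples, with their cytobands and mean log2 fold
changes.  It serves as a printed-input fixture for the consensus stage —
rendering it as a noiseless matrix and re-running the analysis must recover
its flags.
"""

from __future__ import annotations

import pandas as pd

_CONSENSUS_PROFILE = [
    # gene, description, cytoband, mean log2 fold change
    ("POSTN", "periostin, osteoblast specific factor", "13q13.3", -2.21),
    ("MRPL30", "mitochondrial ribosomal protein L30", "2q11.2", -1.98),
    ("ENPP5", "ectonucleotide pyrophosphatase/phosphodiesterase 5", "6p12.3", -1.95),
    ("TGFb3", "transforming growth factor, beta 3", "14q24.3", -1.65),
    ("DDAH1", "dimethylarginine dimethylaminohydrolase 1", "1p22.3", -1.62),
    ("SI", "sucrase-isomaltase", "3q26.1", -1.53),
    ("NEDD9", "human enhancer of filamentation (HEF1/Cas-L)", "6p25-p24", -0.91),
    ("TMCO1", "transmembrane and coiled-coil domains 1", "1q24.2", 1.33),
]


def gist_knockdown_consensus_profile() -> pd.DataFrame:
    """The reference consensus profile (gene, description, cytoband, mean_log2fc)."""
    return pd.DataFrame(
        _CONSENSUS_PROFILE,
        columns=["gene", "description", "cytoband", "mean_log2fc"],
    )


def consensus_profile_matrix(
    n_knockdowns: int = 14, n_controls: int = 2, baseline: float = 8.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noiseless expression matrix realizing the reference consensus profile.

    Each knockdown sample carries exactly the gene's reported mean log2 fold
    change; controls sit at the baseline.  Returns (matrix, sample_annotation).
    """
    profile = gist_knockdown_consensus_profile()
    kd = [f"KD{i + 1:02d}" for i in range(n_knockdowns)]
    con = [f"CON{i + 1:02d}" for i in range(n_controls)]
    values = {s: baseline + profile["mean_log2fc"] for s in kd}
    values.update({s: pd.Series(baseline, index=profile.index) for s in con})
    matrix = pd.DataFrame(values)
    matrix.index = pd.Index(profile["gene"], name="gene")
    annotation = pd.DataFrame(
        {
            "sample": kd + con,
            "group": [f"knockdown_of_{s}" for s in kd] + ["control"] * n_controls,
        }
    )
    return matrix, annotation
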