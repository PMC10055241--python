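"""Annotate molecules with their functional groups by SMARTS matching.

Builds a small manifest of common molecules, labels each against the
37-group extended catalog, and prints the groups found. The printed sets
are what the classifier is trained to recover from an IR spectrum alone.
"""

import pandas as pd

from irfgnet import load_catalog, label_manifest

catalog = load_catalog("extended37")
manifest = pd.DataFrame(
    {
        "id": ["ethanol", "aspirin", "phenol", "benzamide", "methyl-acetate"],
        "smiles": [
            "CCO",
            "CC(=O)Oc1ccccc1C(=O)O",
            "Oc1ccccc1",
            "NC(=O)c1ccccc1",
            "COC(C)=O",
        ],
    }
)

for lv in label_manifest(manifest, catalog):
    print(f"{lv.source_id:>15}: {', '.join(lv.present(catalog))}")
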