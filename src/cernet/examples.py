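"""Published worked-example inputs used by tests and the acceptance script.

``EXAMPLE_DE_ROWS`` reproduces the validated differential-expression rows
of a published atrial-fibrillation left-atrial-appendage screen (4 AF vs
4 sinus-rhythm tissues): fold change (AF/SR), log2 fold change, p-value
and the Up/Down call for the lncRNAs, miRNAs and mRNAs that study carried
into qRT-PCR validation. The table is treated as input data: the package
re-derives the log2FC and regulation columns from FC and p and checks
internal consistency.

``CATALOG_CLASS_COUNTS`` is the same study's published sense/antisense
census of expressed lncRNAs.
"""

EXAMPLE_DE_COLUMNS = ("id", "layer", "FC", "log2FC", "pValue", "Regulation")

EXAMPLE_DE_ROWS = [
    ("XR_001750763.2", "lnc", 25.10239951, 4.649753371, 0.00016291, "Up"),
    ("XR_932105.2", "lnc", 12.9478958, 3.694645755, 2.05e-9, "Up"),
    ("NR_038446.1", "lnc", 8.119639528, 3.02141568, 5.54e-7, "Up"),
    ("ENST00000447009", "lnc", 9.139720493, 3.192150046, 0.000106541, "Up"),
    ("Has-miR-512-3p", "mirna", 0.428858815, -1.221425321, 0.00000915, "Down"),
    ("Has-miR-302c-3p", "mirna", 0.39841765, -1.327646533, 0.001069633, "Down"),
    ("Has-miR-302b-3p", "mirna", 0.276407886, -1.855129318, 0.000399227, "Down"),
    ("TLR2", "mrna", 2.387902301, 1.255743811, 0.0000422, "Up"),
    ("JAK3", "mrna", 2.510805036, 1.328150008, 0.0000272, "Up"),
    ("CCL5", "mrna", 3.193522958, 1.675148822, 0.000175172, "Up"),
    ("VCAM1", "mrna", 2.270942613, 1.18329125, 1.75e-10, "Up"),
]

# published lncRNA orientation census of the same study
CATALOG_CLASS_COUNTS = {"antisense": 19894, "sense": 9171}


def example_de_frame():
    import pandas as pd

    return pd.DataFrame(EXAMPLE_DE_ROWS, columns=EXAMPLE_DE_COLUMNS).set_index("id")
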