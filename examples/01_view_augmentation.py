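"""Enumerate modality-pair views for drug pairs with differing modality
coverage.

Each drug contributes the modalities it actually has; a pair with 8 and 8
available modalities yields 64 views, one with 5 and 4 yields 20.  Views are
the augmentation unit: every view is scored separately and the aggregator
refines the scores into one prediction.
"""

from pairview import MODALITIES, enumerate_views

full = set(MODALITIES)
print(f"both drugs fully characterized : {len(enumerate_views(full, full))} views")

five, four = set(list(MODALITIES)[:5]), set(list(MODALITIES)[:4])
print(f"5 x 4 available modalities     : {len(enumerate_views(five, four))} views")

one = {MODALITIES[0]}
print(f"SMILES-only pair               : {len(enumerate_views(one, one))} view")

# The view count is exactly |A| x |B|: missing modalities shrink the
# augmentation instead of being imputed.
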