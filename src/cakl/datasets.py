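"""Small built-in sequences used in worked examples.

N1_US_P_PRIMER is the US CDC 2019-nCoV nucleocapsid (N1) probe sequence.  The
spatial distribution of its cytosines is the canonical interpretability
example for the facet barcode: the isolated C (position 12) acquires its
first edge at filtration radius 5 and that edge is absorbed into a larger
facet at radius 7.
"""

N1_US_P_PRIMER = "ACCCCGCATTACGTTTGGTGGACC"
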