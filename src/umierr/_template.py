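"""Bundled default simulation template.

A 1-kb synthetic single-stranded template with 50% G+C that passes the
repeat/reverse-complementarity screen (no shared stretch >7 nt within
100 bp nor >5 nt within 25 bp). Regenerate with
``generate_candidates(1, 1000, seed=20210531, max_tries=100,
repair_steps=8000)`` from :mod:`umierr.design`.
"""

DEFAULT_TEMPLATE = (
    "AAAGCGTGGGATTAGCCCGAACTTAGTGGAAACCTCCGGGAATGTTAGAGCTTCCCCGGCTTCGCTAAAGGTCGATTATT"
    "CTTCTCATGCGGACAGCCGCTCATTTAGATAAGGGGCGGGTTCGCGTGATTATGTTCTATTTATCCCCCCTTGGATGCAC"
    "CCTCGGCGGAGGAAAGGCGAATGCACCACTTTACTGCTAGTGCTCCAAGACAACTGCGGGGGCCACACCGAGACCGCTGG"
    "CCTACGGGTCAAGGAATCCGTTGTTAAGGAGGCGGAGGGCATTTGAGTAAGCAAGCTACTGGTTTTGTCTATGCTGTCAG"
    "GCGTACTCGGTTCTCGGACAAATAGATAGTAACTGAAGCGATGAAGGGGGATGGCAACTAAAACCGAGGAGTCCCTGAAG"
    "TTTGATTCAAGTAATGTAAATACGCGAGGCAAGAAAATAGGTTGAGATTCAATCGGGAGGTGTAATGCCGACCCCCGCTT"
    "TGCCACTCGGGCTGTGGAAGCCGCAAGCAGGCAAGGTTTTAGGGTCTCGCGGACAAGGTTATGAAAATTGCACACAAACG"
    "CATAAGAGCTGATGGCTAGAAGCGTAAGCTCGCGTCACATCCCTAAGCATTTCTATGGCGACTAGGGCAGCCAAGTGTCA"
    "CTCACACAGCCCACGTAGACGCTCGGTCACGGGGAATCTAACTCTGAATACTTAGAGTAGAATCTGACGTTTTCCCATCG"
    "GTTCTACTACTCAAATCCGGGAGCTGCGCTTTTCTGGACAAATTAGAGCCGAGTAGCCGCGATATGGAAGAACTAGATGT"
    "GAGAGCTTAATCCTGCCTGGAGGATCTGGACCTCTCGACATGGAAATAACTGCGACACCACTCCACCTCATTCTGCCATA"
    "GCTTTTGATAGTCATTCACTGTCTACAGGTGCTGCAACTTAGCGGTAACCGGATAATCTTCCCCAGTCGGCATAAAATAA"
    "GCTGCTGGAGTAATAGTGTTAATCAGCTTTAGAGTTCCTT"
)
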