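mirna_id
hsa-miR-124-3p
hsa-miR-124-5p
hsa-miR-128-3p
hsa-miR-142-3p
hsa-miR-15b-3p
hsa-miR-17-5p
hsa-miR-18a-3p
hsa-miR-182-5p
hsa-miR-193a-3p
hsa-miR-218-5p
hsa-miR-221-3p
hsa-miR-335-5p
hsa-miR-532-5p
hsa-miR-550a-3p
hsa-miR-625-5p
hsa-miR-633
hsa-miR-638
hsa-miR-708-5p
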