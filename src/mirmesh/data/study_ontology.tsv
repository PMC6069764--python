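child_id	child_label	parent_id
leukemia	Leukemia	neoplasms-by-histologic-type
leukemia-b-cell	Leukemia, B-Cell	leukemia-lymphoid
leukemia-large-granular-lymphocytic	Leukemia, Large Granular Lymphocytic	leukemia-t-cell
leukemia-lymphoid	Leukemia, Lymphoid	leukemia
leukemia-lymphoma-adult-t-cell	Leukemia-Lymphoma, Adult T-Cell	leukemia-t-cell
leukemia-prolymphocytic-t-cell	Leukemia, Prolymphocytic, T-Cell	leukemia-t-cell
leukemia-t-cell	Leukemia, T-Cell	leukemia-lymphoid
neoplasms-by-histologic-type	Neoplasms by Histologic Type	
nervous-system-diseases	Nervous System Diseases	
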