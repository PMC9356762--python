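# ICD-10 underlying-cause-of-death grouping, v1.
# Columns: category <TAB> range_start <TAB> range_end (inclusive).
# 3-character rows match a code's block; 4-character rows (with a dot)
# match at subcode resolution and take precedence over block rules.
RESPIRATORY	J00	J06
RESPIRATORY	J09	J18
RESPIRATORY	J20	J39
RESPIRATORY	J40	J47
RESPIRATORY	J60	J70
RESPIRATORY	J80	J86
RESPIRATORY	J90	J96
RESPIRATORY	J97	J99
RESPIRATORY	R09.2	R09.2
RESPIRATORY	U04	U04
CIRCULATORY	I00	I09
CIRCULATORY	I10	I15
CIRCULATORY	I20	I25
CIRCULATORY	I26	I49
CIRCULATORY	I50	I50
CIRCULATORY	I51	I51
CIRCULATORY	I52	I52
CIRCULATORY	I60	I69
CIRCULATORY	I70	I99
MALIGNANT_NEOPLASM	C00	C97
SENILITY	R54	R54
COVID19	U07.1	U07.1
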