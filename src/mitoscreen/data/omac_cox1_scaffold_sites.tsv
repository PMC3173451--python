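scaffold_id	sample_id	habitat_type	sample_location	coordinates
JCVI_SCAF_1096627235190	GS000b	Open ocean	Sargasso Sea, Station 13 and 11	31°32′10n; 63°35′70w
JCVI_SCAF_1096626936283	GS000d	Open ocean	Sargasso Sea, Station 13	31°32′6n; 63°35′42w
JCVI_SCAF_1096626952824	GS000d	Open ocean	Sargasso Sea, Station 13	31°32′6n; 63°35′42w
JCVI_SCAF_1096628371392	GS001b	Open ocean	Sargasso Sea, Hydrostation S	32°10′00n; 64°30′00w
JCVI_SCAF_1101668018618	GS002	Coastal	Gulf of Maine	42°30′11n; 67°14′24w
JCVI_SCAF_1096626991516	GS018	Open ocean	Rosario Bank	18°2′12n; 83°47′5w
JCVI_SCAF_1096627080744	GS027	Coastal	Devil's Crown, Floreana Island	1°12′58s; 90°25′22w
JCVI_SCAF_1096627330651	GS029	Coastal	North James Bay, Santigo Island	1°12′58s; 90°25′22w
JCVI_SCAF_1096627106753	GS030	Warm seep	Warm seep, Roca Redonda	0°12′0s; 90°50′7w
JCVI_SCAF_1101668499179	GS031	Coastal upwelling	Upwelling, Fernandina Island	0°18′4s; 91°39′6w
JCVI_SCAF_1101668505444	GS031	Coastal upwelling	Upwelling, Fernandina Island	0°18′4s; 91°39′6w
JCVI_SCAF_1096627164454	GS036	Coastal	Cabo Marshall, Isabella Island	0°35′38s; 91°4′10w
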