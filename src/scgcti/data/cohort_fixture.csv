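patient_id,diagnosis,waveform,ejection_fraction
C001,MI,T,55.0
C002,MI,T,55.0
C003,MI,T,55.0
C004,MI,T,55.0
C005,MI,T,55.0
C006,MI,T,55.0
C007,MI,T,55.0
C008,MI,T,55.0
C009,MI,T,45.0
C010,MI,T,45.0
C011,MI,T,45.0
C012,MI,T,45.0
C013,MI,T,45.0
C014,MI,T,45.0
C015,MI,T,45.0
C016,MI,T,45.0
C017,MI,T,45.0
C018,MI,T,45.0
C019,MI,T,45.0
C020,MI,T,45.0
C021,MI,T,45.0
C022,MI,T,45.0
C023,MI,T,33.0
C024,MI,T,33.0
C025,MI,T,33.0
C026,MI,T,33.0
C027,HF,T,33.0
C028,HF,T,33.0
C029,HF,T,33.0
C030,HF,T,33.0
C031,HF,T,33.0
C032,HF,T,33.0
C033,HF,T,33.0
C034,HF,T,33.0
C035,HF,T,33.0
C036,HF,T,33.0
C037,HF,T,33.0
C038,HF,T,33.0
C039,HF,T,33.0
C040,HF,T,33.0
C041,HF,T,33.0
C042,HF,T,33.0
C043,HF,T,33.0
C044,HF,T,33.0
C045,HF,T,33.0
C046,HF,T,33.0
C047,HF,T,33.0
C048,HF,T,33.0
C049,HF,T,33.0
C050,HF,T,33.0
C051,HF,T,33.0
C052,HF,T,33.0
C053,HF,T,33.0
C054,TX,T,
C055,TX,T,
C056,TX,T,
C057,MI,NT,55.0
C058,MI,NT,55.0
C059,MI,NT,55.0
C060,MI,NT,55.0
C061,MI,NT,55.0
C062,MI,NT,45.0
C063,MI,NT,45.0
C064,MI,NT,45.0
C065,HF,NT,45.0
C066,HF,NT,45.0
C067,HF,NT,45.0
C068,HF,NT,45.0
C069,HF,NT,33.0
C070,HF,NT,33.0
C071,HF,NT,33.0
C072,HF,NT,33.0
C073,HF,NT,33.0
C074,HF,NT,33.0
C075,HF,NT,33.0
C076,HF,NT,33.0
C077,HF,NT,33.0
C078,HF,NT,33.0
C079,HF,NT,33.0
C080,HF,NT,33.0
C081,HF,NT,33.0
C082,HF,NT,33.0
C083,HF,NT,33.0
C084,HF,NT,33.0
C085,HF,NT,33.0
C086,HF,NT,33.0
C087,TX,NT,33.0
C088,TX,NT,33.0
C089,TX,NT,33.0
C090,TX,NT,
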