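farm_id,category
I001,abandon
I002,abandon
I003,abandon
I004,abandon
I005,abandon
I006,abandon
I007,abandon
I008,abandon
I009,abandon
I010,abandon
I011,abandon
I012,abandon
I013,abandon
I014,abandon
I015,abandon
I016,abandon
I017,abandon
I018,abandon
I019,abandon
I020,abandon
I021,abandon
I022,abandon
I023,abandon
I024,abandon
I025,abandon
I026,abandon
I027,abandon
I028,abandon
I029,abandon
I030,abandon
I031,abandon
I032,abandon
I033,abandon
I034,abandon
I035,abandon
I036,abandon
I037,abandon
I038,abandon
I039,abandon
I040,abandon
I041,abandon
I042,abandon
I043,abandon
I044,abandon
I045,abandon
I046,abandon
I047,abandon
I048,abandon
I049,abandon
I050,abandon
I051,abandon
I052,abandon
I053,abandon
I054,abandon
I055,abandon
I056,abandon
I057,abandon
I058,dump
I059,dump
I060,dump
I061,dump
I062,dump
I063,dump
I064,dump
I065,dump
I066,feeding_station
I067,feeding_station
I068,feeding_station
I069,collection_service
I070,collection_service
I071,collection_service
I072,collection_service
I073,collection_service
I074,collection_service
I075,collection_service
I076,collection_service
I077,collection_service
I078,collection_service
I079,collection_service
I080,collection_service
I081,collection_service
I082,collection_service
I083,collection_service
I084,collection_service
I085,collection_service
I086,collection_service
I087,collection_service
I088,collection_service
I089,collection_service
I090,buried
I091,buried
I092,mortuary
I093,never
I094,never
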