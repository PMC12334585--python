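# Default POI category -> activity type mapping.
# First-level Gowalla-style categories plus a handful of second-level
# refinements (Residence has no first-level category of its own and must come
# from second-level entries; nightlife folds into Entertainment). Edit this
# file to match the taxonomy of a concrete deposit.
category_id,activity_type
community,Community
entertainment,Entertainment
food,Food
nightlife,Entertainment
outdoors,Outdoors
shopping,Shopping
travel,Travel
community:home,Residence
community:apartment,Residence
community:dorm,Residence
community:office,Community
community:school,Community
entertainment:cinema,Entertainment
entertainment:theatre,Entertainment
entertainment:stadium,Entertainment
nightlife:bar,Entertainment
nightlife:club,Entertainment
food:restaurant,Food
food:cafe,Food
food:diner,Food
outdoors:park,Outdoors
outdoors:trail,Outdoors
shopping:mall,Shopping
shopping:grocery,Shopping
travel:airport,Travel
travel:station,Travel
travel:hotel,Travel
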